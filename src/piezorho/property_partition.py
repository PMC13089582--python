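"""Radical/conservative partitioning of codon changes by an amino-acid property.

The substitution process splits nonsynonymous changes into *conservative* and
*radical* classes according to how strongly they shift a physicochemical
property — here, per-residue compressibility K0, whose magnitude is expected to
track pressure-induced structural deformation. Because no biologically obvious
cutoff exists, candidate partitions are built by ranking every nonsynonymous
codon change reachable by a single nucleotide substitution on \\|dK0\\| and
designating the top P% as radical, for P on a 10..90 grid; model comparison
downstream picks the partition.

Events are ranked at the level of unordered codon-pair events (forward and
reverse collapse to one event; both share \\|dK0\\|), and ties at the boundary
are resolved inclusively: every event with \\|dK0\\| >= the threshold value is
radical, which keeps the classification deterministic and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .genetics import STANDARD_CODE, GeneticCode

P_GRID = tuple(range(10, 100, 10))

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AminoAcidPropertyScale:
    """A 20-value amino-acid property scale (K0 compressibility by default).

    values: one-letter code -> property value, units m^3 mol^-1 Pa^-1 x 1e-15
    for the packaged compressibility scale; any complete 20-value scale works.
    """

    values: dict[str, float]
    name: str = "K0"

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale '{self.name}' missing amino acids: {sorted(missing)}")
        bad = {a: v for a, v in self.values.items() if not math.isfinite(float(v))}
        if bad:
            raise ValueError(f"scale '{self.name}' has non-finite entries: {bad}")

    def __getitem__(self, aa: str) -> float:
        try:
            return float(self.values[aa])
        except KeyError:
            raise KeyError(f"amino acid {aa!r} absent from scale '{self.name}'") from None

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "AminoAcidPropertyScale":
        """Read a 2-column delimited file (one-letter code, value); '#' comments
        and an optional header line are skipped."""
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < 2:
                raise ValueError(f"malformed scale line: {line!r}")
            aa, raw = fields[0], fields[1]
            if len(aa) != 1 or not aa.isalpha():
                continue  # header
            try:
                values[aa.upper()] = float(raw)
            except ValueError:
                continue  # header line like "aa K0"
        return cls(values=values, name=name or Path(path).stem)

    @classmethod
    def packaged_k0(cls) -> "AminoAcidPropertyScale":
        """The packaged synthetic compressibility-magnitude scale.

        A reconstruction anchored to reported substitution deltas, not a
        transcription of a published table; see the data file header.
        """
        ref = resources.files("piezorho.data") / "k0_scale_synthetic.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path, name="K0-synthetic")


@dataclass(frozen=True)
class SubstitutionEvent:
    """One nonsynonymous codon change reachable by a single nucleotide change."""

    from_codon: str
    to_codon: str
    from_aa: str
    to_aa: str
    delta_K0: float | None = None

    @property
    def abs_delta_K0(self) -> float:
        if self.delta_K0 is None:
            raise ValueError("event has no property delta attached")
        return abs(self.delta_K0)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.from_codon, self.to_codon))


def single_step_nonsynonymous_pairs(code: GeneticCode = STANDARD_CODE) -> list[SubstitutionEvent]:
    """All ordered nonsynonymous sense-codon changes differing at one position.

    Stop codons never appear (the code object carries sense codons only);
    synonymous single-step changes are excluded.
    """
    events = []
    for i, j, _pos, _ts in code.single_step_neighbours():
        ci, cj = code.codons[i], code.codons[j]
        ai, aj = code.aa(ci), code.aa(cj)
        if ai != aj:
            events.append(SubstitutionEvent(ci, cj, ai, aj))
    return events


def delta_property(event: SubstitutionEvent, scale: AminoAcidPropertyScale) -> float:
    """Signed property change K0(to) - K0(from); antisymmetric under reversal."""
    return scale[event.to_aa] - scale[event.from_aa]


def annotate_events(events, scale: AminoAcidPropertyScale) -> list[SubstitutionEvent]:
    return [
        SubstitutionEvent(e.from_codon, e.to_codon, e.from_aa, e.to_aa, delta_property(e, scale))
        for e in events
    ]


@dataclass(frozen=True)
class RadicalPartition:
    """Radical/conservative classification of every single-step nonsynonymous
    sense-codon pair at a given top-P% cutoff on \\|dK0\\|."""

    P: int
    threshold: float
    classes: dict[frozenset, str] = field(repr=False)
    scale_name: str = "K0"

    def classify(self, from_codon: str, to_codon: str) -> str:
        try:
            return self.classes[frozenset((from_codon, to_codon))]
        except KeyError:
            raise KeyError(
                f"codon pair {from_codon}->{to_codon} is not a single-step "
                "nonsynonymous sense-codon change"
            ) from None

    def is_radical(self, from_codon: str, to_codon: str) -> bool:
        return self.classify(from_codon, to_codon) == "radical"

    @property
    def radical_pairs(self) -> set:
        return {p for p, c in self.classes.items() if c == "radical"}

    def to_frame(self, code: GeneticCode = STANDARD_CODE,
                 scale: AminoAcidPropertyScale | None = None) -> pd.DataFrame:
        """Partition report: one row per ordered event."""
        scale = scale or AminoAcidPropertyScale.packaged_k0()
        rows = []
        for e in annotate_events(single_step_nonsynonymous_pairs(code), scale):
            rows.append(
                dict(from_codon=e.from_codon, to_codon=e.to_codon,
                     from_aa=e.from_aa, to_aa=e.to_aa, delta_K0=e.delta_K0,
                     **{"class": self.classes[e.pair]})
            )
        return pd.DataFrame(rows)


def build_partition(scale: AminoAcidPropertyScale, P: int,
                    code: GeneticCode = STANDARD_CODE,
                    allow_off_grid: bool = False) -> RadicalPartition:
    """Rank unordered single-step nonsynonymous codon-pair events by \\|dK0\\|
    and label the top P% radical (inclusive threshold on ties)."""
    if P not in P_GRID and not allow_off_grid:
        raise ValueError(f"P={P} outside the standard grid {P_GRID}; "
                         "pass allow_off_grid=True to override")
    if not 0 < P < 100:
        raise ValueError(f"P={P} must be strictly between 0 and 100")
    events = annotate_events(single_step_nonsynonymous_pairs(code), scale)
    by_pair: dict[frozenset, float] = {}
    for e in events:
        by_pair[e.pair] = e.abs_delta_K0
    ranked = sorted(by_pair.values(), reverse=True)
    n = len(ranked)
    k = max(1, int(round(P / 100 * n)))
    threshold = ranked[k - 1]
    classes = {
        pair: ("radical" if v >= threshold else "conservative")
        for pair, v in by_pair.items()
    }
    return RadicalPartition(P=P, threshold=threshold, classes=classes,
                            scale_name=scale.name)
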