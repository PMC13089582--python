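"""Genetic-code bookkeeping shared by the codon model machinery.

Thin wrapper over :mod:`Bio.Data.CodonTable`: fixes a canonical ordering of the
sense codons and precomputes the single-nucleotide neighbour structure that the
rate matrix and the substitution-event enumeration both need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T point change."""
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons, in a fixed order.

    ``codons`` are sorted lexicographically (ACGT alphabet); stop codons are
    excluded entirely — changes to or from a stop codon get rate zero
    downstream and never appear in substitution-event lists.
    """

    name: str
    codons: tuple[str, ...]
    stop_codons: frozenset[str]
    codon_to_aa: dict[str, str] = field(repr=False)

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(table.forward_table)
        if len(forward) + len(table.stop_codons) != 64:
            raise ValueError(
                f"genetic code table {table_id} does not cover all 64 codons"
            )
        codons = tuple(sorted(forward))
        return cls(
            name=table.names[0] if table.names else str(table_id),
            codons=codons,
            stop_codons=frozenset(table.stop_codons),
            codon_to_aa=forward,
        )

    def __post_init__(self):
        if len(self.codons) != len(set(self.codons)):
            raise ValueError("duplicate codons in genetic code")
        missing = {c for c in self.codons if c not in self.codon_to_aa}
        if missing:
            raise ValueError(f"codons without amino acid assignment: {missing}")

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def index(self, codon: str) -> int:
        return self.codons.index(codon)

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    @property
    def amino_acids(self) -> frozenset[str]:
        return frozenset(self.codon_to_aa.values())

    def single_step_neighbours(self):
        """Yield ordered pairs (i, j, pos, transition?) of sense-codon indices
        differing at exactly one nucleotide position."""
        codons = self.codons
        for i, ci in enumerate(codons):
            for j, cj in enumerate(codons):
                if i == j:
                    continue
                diffs = [p for p in range(3) if ci[p] != cj[p]]
                if len(diffs) == 1:
                    p = diffs[0]
                    yield i, j, p, is_transition(ci[p], cj[p])


STANDARD_CODE = GeneticCode.from_ncbi_id(1)
SENSE_CODONS = STANDARD_CODE.codons


def codon_index_array(sequence: str, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Map a nucleotide string to an int array of codon indices.

    Codons containing gaps or ambiguity characters, and (where permitted by
    caller policy) stop codons, are encoded as -1 = missing data.
    """
    if len(sequence) % 3:
        raise ValueError("sequence length not divisible by 3")
    seq = sequence.upper().replace("U", "T")
    lookup = {c: i for i, c in enumerate(code.codons)}
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(len(out)):
        out[k] = lookup.get(seq[3 * k : 3 * k + 3], -1)
    return out
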