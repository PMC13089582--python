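"""Codon alignments: FASTA-backed, validated, with a missing-data policy.

Sequences must share a common length divisible by 3. Gaps and ambiguity codes
are treated as missing data (partial likelihood one over all sense codons).
Internal stop codons are a hard error by default; ``stop_policy="missing"``
downgrades them to missing data with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import STANDARD_CODE, GeneticCode, codon_index_array


@dataclass
class CodonAlignment:
    """An in-frame codon alignment over an ordered set of taxa."""

    taxa: list[str]
    sequences: dict[str, str] = field(repr=False)
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self):
        if not self.taxa:
            raise ValueError("empty alignment")
        lengths = {len(self.sequences[t]) for t in self.taxa}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[self.taxa[0]]) // 3

    def codon_matrix(self, stop_policy: str = "error") -> np.ndarray:
        """(n_taxa, n_codons) int matrix of sense-codon indices, -1 = missing."""
        rows = []
        for taxon in self.taxa:
            seq = self.sequences[taxon].upper().replace("U", "T")
            idx = codon_index_array(seq, self.code)
            for k in np.flatnonzero(idx < 0):
                codon = seq[3 * k : 3 * k + 3]
                if codon in self.code.stop_codons:
                    if stop_policy == "error":
                        raise ValueError(
                            f"internal stop codon {codon} in {taxon!r} at codon "
                            f"site {k + 1}"
                        )
                    warnings.warn(
                        f"stop codon {codon} in {taxon!r} at site {k + 1} "
                        "treated as missing data"
                    )
            rows.append(idx)
        return np.vstack(rows)

    @classmethod
    def from_fasta(cls, path, code: GeneticCode = STANDARD_CODE) -> "CodonAlignment":
        taxa, sequences = [], {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate taxon label {record.id!r}")
            if len(record.seq) % 3:
                raise ValueError(
                    f"sequence length {len(record.seq)} of taxon {record.id!r} "
                    "not divisible by 3"
                )
            taxa.append(record.id)
            sequences[record.id] = str(record.seq)
        return cls(taxa=taxa, sequences=sequences, code=code)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[t]), id=t, description="") for t in self.taxa
        ]
        SeqIO.write(records, str(path), "fasta")

    def subset_taxa(self, taxa) -> "CodonAlignment":
        return CodonAlignment(
            taxa=list(taxa), sequences={t: self.sequences[t] for t in taxa},
            code=self.code,
        )


def read_codon_alignment(path, code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    """Read and validate a codon-aligned FASTA file (spec op)."""
    return CodonAlignment.from_fasta(path, code=code)
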