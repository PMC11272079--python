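"""In-frame codon alignments: container, validation, FASTA/PHYLIP input/output.

The container trusts the reading frame of its input (column 0 is codon
position 1) and rejects internal stop codons, which would place the
sequence outside the sense-codon state space of the substitution models.
A trailing stop codon shared by all rows is *not* silently stripped; inputs
are expected to be coding sequence without the terminator, as produced by
ortholog-alignment pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from ._codons import codon_index, is_stop


class AlignmentError(ValueError):
    """Ragged rows, duplicate taxa, or a length not divisible by three."""


class FrameError(ValueError):
    """An internal stop codon under the declared genetic code."""


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences, one row per taxon.

    Parameters
    ----------
    taxa : list of str
        Unique taxon names, in row order.
    sequences : list of str
        Upper-case nucleotide strings, all of equal length divisible by 3.
    code : str
        Genetic-code identifier (default ``"universal"``).
    """

    taxa: list[str]
    sequences: list[str]
    code: str = "universal"
    _index: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("taxon names are not unique")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(f"alignment length {length} not divisible by 3")
        for taxon, seq in zip(self.taxa, self.sequences):
            for k in range(0, length, 3):
                codon = seq[k : k + 3]
                if is_stop(codon, self.code):
                    raise FrameError(
                        f"internal stop codon {codon} in taxon {taxon!r} "
                        f"at codon index {k // 3}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_codons) integer matrix over the sense-codon states.

        Codons containing gaps or ambiguity characters map to -1 and are
        treated as missing data by the likelihood machinery.
        """
        if self._index is None:
            idx = codon_index(self.code)
            out = np.full((self.n_taxa, self.n_codons), -1, dtype=np.int64)
            for i, seq in enumerate(self.sequences):
                for j in range(self.n_codons):
                    out[i, j] = idx.get(seq[3 * j : 3 * j + 3], -1)
            self._index = out
        return self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonAlignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.sequences == other.sequences
            and self.code == other.code
        )


def read_codon_alignment(path, format: str = "fasta", code: str = "universal") -> CodonAlignment:
    """Read a codon alignment from FASTA or sequential PHYLIP.

    Raises :class:`AlignmentError` for ragged input and :class:`FrameError`
    for internal stop codons.
    """
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif format == "phylip":
        aln = AlignIO.read(str(path), "phylip-sequential")
        taxa = [r.id for r in aln]
        seqs = [str(r.seq) for r in aln]
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return CodonAlignment(taxa, seqs, code=code)


def write_codon_alignment(aln: CodonAlignment, path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in zip(aln.taxa, aln.sequences)
    ]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "phylip-sequential")
    else:
        raise ValueError(f"unknown alignment format {format!r}")
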