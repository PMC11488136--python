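"""Reference multiple sequence alignment container and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MSA_ALPHABET = set("ACGTN-")


class MsaError(ValueError):
    pass


@dataclass
class ReferenceMsa:
    """Aligned reference mitogenomes, one record per taxon-tree node.

    All sequences have equal length over {A,C,G,T,N,-}; names are unique and
    every column carries at least one non-gap character.
    """

    names: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.seqs):
            raise MsaError("names and sequences differ in number")
        if len(self.names) < 2:
            raise MsaError("an alignment needs at least 2 records")
        if len(set(self.names)) != len(self.names):
            raise MsaError("duplicate record names")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise MsaError(f"unequal aligned lengths: {sorted(lengths)}")
        bad = set("".join(self.seqs)) - MSA_ALPHABET
        if bad:
            raise MsaError(f"invalid characters in alignment: {sorted(bad)}")
        for j in range(self.length):
            if all(s[j] == "-" for s in self.seqs):
                raise MsaError(f"column {j} is all gaps")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.names)

    def record(self, name: str) -> str:
        try:
            return self.seqs[self.names.index(name)]
        except ValueError:
            raise MsaError(f"no record named {name!r}") from None

    def degapped(self, name: str) -> str:
        return self.record(name).replace("-", "")

    def extended(self, names: list[str], seqs: list[str]) -> "ReferenceMsa":
        return ReferenceMsa(self.names + list(names), self.seqs + list(seqs))

    @classmethod
    def from_fasta(cls, path) -> "ReferenceMsa":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        if not names:
            raise MsaError(f"no FASTA records in {path}")
        return cls(names, seqs)

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(s), id=n, description="") for n, s in zip(self.names, self.seqs)]
        SeqIO.write(recs, str(path), "fasta")
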