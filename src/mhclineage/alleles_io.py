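"""Reading, validation and masking of aligned MHC allele coding sequences.

Allele sets are in-frame nucleotide alignments whose records carry IMGT-style
names such as ``HLA-DRB1*03:01``.  A :class:`RegionMask` selects codons (for
example the 27 peptide-binding-region codons) so that analyses can be run on
the PBR, on the non-PBR remainder, or on the whole alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTN-")

_NAME_RE = re.compile(
    r"^(?P<prefix>[A-Za-z]+)-(?P<locus>[A-Za-z0-9]+)\*(?P<fields>[0-9]+(?::[0-9]+)*)$"
)


class AlignmentError(ValueError):
    """Sequences do not form a valid equal-length alignment."""


class FrameError(ValueError):
    """Alignment length is not a whole number of codons."""


class AlphabetError(ValueError):
    """Sequence contains characters outside A, C, G, T, N, ``-``."""


class MaskError(ValueError):
    """Region-mask position falls outside the alignment."""


@dataclass(frozen=True)
class AlleleName:
    """Parsed IMGT-style allele name.

    ``HLA-DRB1*11:01`` parses to species prefix ``HLA``, locus ``DRB1`` and
    numeric fields ``("11", "01")``; the first field is the allelic lineage.
    Names that are not IMGT-style are kept verbatim with empty parts.
    """

    raw: str
    species_prefix: str = ""
    locus: str = ""
    fields: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _NAME_RE.match(text.strip())
        if m is None:
            return cls(raw=text.strip())
        return cls(
            raw=text.strip(),
            species_prefix=m.group("prefix"),
            locus=m.group("locus"),
            fields=tuple(m.group("fields").split(":")),
        )

    @property
    def lineage(self) -> str:
        """First name field (e.g. ``03`` for ``HLA-DRB1*03:01``)."""
        return self.fields[0] if self.fields else ""

    @property
    def is_imgt(self) -> bool:
        return bool(self.fields)

    def format(self) -> str:
        if not self.is_imgt:
            return self.raw
        return f"{self.species_prefix}-{self.locus}*{':'.join(self.fields)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


@dataclass
class AlleleSet:
    """Equal-length, in-frame nucleotide alignment with parsed names."""

    names: list[AlleleName]
    sequences: list[str]
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences differ in count")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.sequences:
            n = len(self.sequences[0])
            if n % 3 != 0:
                raise FrameError(f"alignment length {n} is not a multiple of 3")
        for name, seq in zip(self.names, self.sequences):
            bad = set(seq.upper()) - VALID_CHARS
            if bad:
                raise AlphabetError(
                    f"{name.raw}: illegal characters {sorted(bad)}"
                )
        self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.alignment_length // 3

    def name_strings(self) -> list[str]:
        return [n.raw for n in self.names]

    def codon(self, seq_index: int, codon_index: int) -> str:
        """Codon at 0-based codon position ``codon_index``."""
        s = self.sequences[seq_index]
        return s[3 * codon_index : 3 * codon_index + 3]

    def incomplete_codon_columns(self) -> set[int]:
        """0-based codon columns containing a gap or N in any sequence."""
        out: set[int] = set()
        for c in range(self.n_codons):
            for s in self.sequences:
                cod = s[3 * c : 3 * c + 3]
                if "-" in cod or "N" in cod:
                    out.add(c)
                    break
        return out

    def subset(self, keep: Iterable[str]) -> "AlleleSet":
        keep = set(keep)
        names, seqs = [], []
        for n, s in zip(self.names, self.sequences):
            if n.raw in keep:
                names.append(n)
                seqs.append(s)
        labels = {k: v for k, v in self.group_labels.items() if k in keep}
        return AlleleSet(names=names, sequences=seqs, group_labels=labels)


@dataclass(frozen=True)
class RegionMask:
    """Set of 1-based mature-protein codon positions plus a leader offset.

    ``offset`` is the number of signal-peptide codons preceding the mature
    protein in the alignment; mask position ``p`` addresses alignment codon
    ``p + offset`` (1-based).  DRB1 complete CDS carry a 29-codon leader, so
    the shipped PBR mask is used with ``offset=29`` on full CDS and
    ``offset=0`` on alignments that already start at the mature protein.
    """

    codon_positions: frozenset[int]
    offset: int = 0

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.codon_positions):
            raise MaskError("mask positions must be positive (1-based)")

    def alignment_codons(self, n_codons: int) -> set[int]:
        """0-based alignment codon indices covered by the mask."""
        out = set()
        for p in sorted(self.codon_positions):
            idx = p + self.offset  # 1-based alignment codon
            if not (1 <= idx <= n_codons):
                raise MaskError(
                    f"mask position {p} (alignment codon {idx}) outside "
                    f"1..{n_codons}"
                )
            out.add(idx - 1)
        return out


def parse_allele_name(text: str) -> AlleleName:
    return AlleleName.parse(text)


def read_fasta(path: str | Path) -> AlleleSet:
    """Read an aligned multi-FASTA into an :class:`AlleleSet`.

    Raises :class:`AlignmentError` on ragged lengths, :class:`FrameError`
    when the length is not a multiple of three, and :class:`AlphabetError`
    on characters outside ``{A,C,G,T,N,-}``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    names = [AlleleName.parse(r.description.split()[0]) for r in records]
    seqs = [str(r.seq) for r in records]
    return AlleleSet(names=names, sequences=seqs)


def write_fasta(a: AlleleSet, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=n.raw, description="")
        for n, s in zip(a.names, a.sequences)
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_mask(path: str | Path, offset: int = 0) -> RegionMask:
    """Read a mask file: one 1-based codon position per line, ``#`` comments."""
    positions = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        positions.add(int(line))
    return RegionMask(codon_positions=frozenset(positions), offset=offset)


def default_pbr_mask(offset: int = 0) -> RegionMask:
    """The shipped 27-codon peptide-binding-region mask (editable data file)."""
    ref = resources.files("mhclineage.data") / "pbr_mask_drb1.txt"
    positions = set()
    for line in ref.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            positions.add(int(line))
    return RegionMask(codon_positions=frozenset(positions), offset=offset)


def apply_region_mask(
    a: AlleleSet, m: RegionMask, mode: str = "exclude"
) -> AlleleSet:
    """Keep (``include``) or remove (``exclude``) the masked codons.

    Codon boundaries are preserved: whole codons are kept or dropped.
    """
    if mode not in ("include", "exclude"):
        raise ValueError(f"mode must be include or exclude, got {mode!r}")
    masked = m.alignment_codons(a.n_codons)
    if mode == "include":
        keep = sorted(masked)
    else:
        keep = [c for c in range(a.n_codons) if c not in masked]
    seqs = ["".join(s[3 * c : 3 * c + 3] for c in keep) for s in a.sequences]
    return AlleleSet(
        names=list(a.names), sequences=seqs, group_labels=dict(a.group_labels)
    )


def name_report(a: AlleleSet) -> "pd.DataFrame":
    """TSV-ready table of parsed allele names."""
    import pandas as pd

    rows = []
    for n in a.names:
        rows.append(
            {
                "name": n.raw,
                "species_prefix": n.species_prefix,
                "locus": n.locus,
                "lineage": n.lineage,
                "fields": ":".join(n.fields),
                "imgt_style": n.is_imgt,
            }
        )
    return pd.DataFrame(rows)
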