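"""Tri-nucleotide substitution contexts and panel annotation.

Low-frequency sequencing errors are strongly patterned by local sequence
context: the substituted base together with its immediate 5' and 3'
neighbours.  Collapsing strands so that the substituted base is always a
pyrimidine (the convention used for COSMIC mutational signatures) leaves
6 distinguishable substitutions (C>A, C>G, C>T, T>A, T>C, T>G) and 16
flank combinations each — 96 tri-nucleotide contexts (TNCs) in total.
These classes index the empirical-Bayes priors of the error model.

A :class:`Panel` holds the targeted regions as per-base records with
their reference tri-nucleotide context.  Positions at contig edges or
with an ``N`` in the context cannot be assigned a TNC; they are kept and
flagged ``unmodeled`` rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")

#: Canonical substitution order used for enumeration and reporting.
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G; N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class TncKey(NamedTuple):
    """One of the 96 canonical tri-nucleotide substitution classes.

    ``trinucleotide`` is the pyrimidine-centered reference 3-mer,
    ``ref`` its center base (C or T) and ``alt`` the substituted base.
    """

    trinucleotide: str
    ref: str
    alt: str

    @property
    def label(self) -> str:
        """COSMIC-style label, e.g. ``A[C>T]G``."""
        t = self.trinucleotide
        return f"{t[0]}[{self.ref}>{self.alt}]{t[2]}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_contexts() -> list[TncKey]:
    """All 96 canonical TNC keys in a fixed, documented order.

    Substitutions are ordered C>A, C>G, C>T, T>A, T>C, T>G; within a
    substitution the 16 flank pairs are lexicographic (A < C < G < T),
    5' flank varying slowest.  The first key is ``A[C>A]A``.
    """
    keys = []
    for ref, alt in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                keys.append(TncKey(five + ref + three, ref, alt))
    return keys


def canonical_key(context: str, ref_center: str, alt: str) -> TncKey:
    """Map a (reference 3-mer, alternate allele) pair to its canonical TNC.

    Purine-centered inputs are reverse-complemented so the substituted
    base is a pyrimidine; pyrimidine-centered inputs pass through.

    Raises
    ------
    ValueError
        If the context is not a 3-mer over ACGT, its center differs from
        ``ref_center``, or ``alt`` equals ``ref_center`` — all of which
        mark the position as unusable for modeling.
    """
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValueError(f"context {context!r} is not a 3-mer over ACGT")
    if context[1] != ref_center:
        raise ValueError(
            f"context center {context[1]!r} does not match reference {ref_center!r}"
        )
    if alt not in BASES:
        raise ValueError(f"alternate allele {alt!r} is not one of ACGT")
    if alt == ref_center:
        raise ValueError("alternate allele equals the reference base")
    if ref_center in PYRIMIDINES:
        return TncKey(context, ref_center, alt)
    return TncKey(
        reverse_complement(context),
        reverse_complement(ref_center),
        reverse_complement(alt),
    )


def _label_lookup() -> dict[tuple[str, str], str]:
    """Precomputed (context, alt) -> canonical label map for all 192 pairs."""
    table: dict[tuple[str, str], str] = {}
    for five in BASES:
        for center in BASES:
            for three in BASES:
                ctx = five + center + three
                for alt in BASES:
                    if alt == center:
                        continue
                    table[(ctx, alt)] = canonical_key(ctx, center, alt).label
    return table


_LABELS = _label_lookup()


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED regions (0-based half-open; 3+ columns, extras ignored)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"empty or inverted BED region {chrom}:{start}-{end}")
            regions.append((chrom, start, end))
    return regions


@dataclass
class Panel:
    """Annotated target panel: one record per base in the region union.

    ``positions`` columns: chrom, pos (1-based), ref, context (reference
    3-mer, empty when undefined), modeled (bool), reason (why a position
    is unmodeled: ``edge`` or ``contains_N``).
    """

    positions: pd.DataFrame
    _alts: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "context", "modeled", "reason"}
        missing = required - set(self.positions.columns)
        if missing:
            raise ValueError(f"panel table missing columns {sorted(missing)}")
        self.positions = self.positions.reset_index(drop=True)

    # -- construction -------------------------------------------------

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str],
        regions: Sequence[tuple[str, int, int]] | None = None,
    ) -> "Panel":
        """Build a panel from in-memory contigs and 0-based half-open regions.

        With ``regions=None`` every base of every contig is targeted.
        """
        if regions is None:
            regions = [(c, 0, len(s)) for c, s in sequences.items()]
        per_contig: dict[str, set[int]] = {}
        for chrom, start, end in regions:
            if chrom not in sequences:
                raise KeyError(f"region contig {chrom!r} absent from reference")
            if start < 0 or end > len(sequences[chrom]):
                raise ValueError(
                    f"region {chrom}:{start}-{end} outside reference bounds "
                    f"(contig length {len(sequences[chrom])})"
                )
            per_contig.setdefault(chrom, set()).update(range(start + 1, end + 1))
        records = []
        for chrom in per_contig:
            seq = sequences[chrom].upper()
            for pos in sorted(per_contig[chrom]):
                ref = seq[pos - 1]
                if pos == 1 or pos == len(seq):
                    context, modeled, reason = "", False, "edge"
                else:
                    context = seq[pos - 2 : pos + 1]
                    if any(b not in BASES for b in context):
                        modeled, reason = False, "contains_N"
                    else:
                        modeled, reason = True, ""
                records.append((chrom, pos, ref, context, modeled, reason))
        df = pd.DataFrame(
            records, columns=["chrom", "pos", "ref", "context", "modeled", "reason"]
        )
        return cls(df)

    @classmethod
    def from_fasta_bed(cls, fasta: str | Path, bed: str | Path) -> "Panel":
        """Build a panel from an (indexed) FASTA reference and a BED file."""
        from pyfaidx import Fasta

        ref = Fasta(str(fasta))
        regions = read_bed(bed)
        sequences: dict[str, str] = {}
        for chrom, _, _ in regions:
            if chrom not in ref:
                raise KeyError(f"region contig {chrom!r} absent from reference FASTA")
            if chrom not in sequences:
                sequences[chrom] = str(ref[chrom][:])
        return cls.from_sequences(sequences, regions)

    # -- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.positions.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Panel":
        df = pd.read_csv(
            path, sep="\t", dtype={"chrom": str, "context": str, "reason": str},
            keep_default_na=False,
        )
        df["pos"] = df["pos"].astype(int)
        df["modeled"] = df["modeled"].astype(str).str.lower().isin(("true", "1"))
        return cls(df)

    # -- views ---------------------------------------------------------

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_modeled(self) -> int:
        return int(self.positions["modeled"].sum())

    def alt_table(self) -> pd.DataFrame:
        """Long table with one row per (modeled position, alternate allele).

        Columns: pos_index (row in ``positions``), chrom, pos, ref, alt,
        tnc (canonical label).  Cached after first call.
        """
        if self._alts is not None:
            return self._alts
        modeled = self.positions[self.positions["modeled"]]
        rows = []
        for idx, chrom, pos, ref, ctx in zip(
            modeled.index, modeled["chrom"], modeled["pos"],
            modeled["ref"], modeled["context"],
        ):
            for alt in BASES:
                if alt == ref:
                    continue
                rows.append((idx, chrom, pos, ref, alt, _LABELS[(ctx, alt)]))
        self._alts = pd.DataFrame(
            rows, columns=["pos_index", "chrom", "pos", "ref", "alt", "tnc"]
        )
        return self._alts


def annotate_panel(fasta: str | Path, bed: str | Path) -> Panel:
    """Functional alias for :meth:`Panel.from_fasta_bed`."""
    return Panel.from_fasta_bed(fasta, bed)
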