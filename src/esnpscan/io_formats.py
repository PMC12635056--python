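"""Readers/writers for the external formats the pipeline touches, plus sequence encoding.

Coordinate convention: everything in memory is 0-based half-open (BED-native).
VCF and variant TSV positions are 1-based on disk and converted at the boundary
(subtract 1 from the position / start only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Row order of every one-hot / PWM matrix in the package.
BASE_ORDER = "ACGT"


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class VariantRecord:
    """A biallelic SNV with two-population alternate-allele frequencies.

    ``af_ea`` / ``af_aa`` are alternate-allele frequencies in the European- and
    African-ancestry panels.  After orientation to the EA major allele
    (``population_filter.orient_to_ea_major``) ``af_ea <= 0.5`` holds.
    """

    id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    af_ea: float
    af_aa: float
    fst: float | None = None
    dominance: Literal["AA", "EA", "none"] | None = None

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or len(self.ref) != 1:
            raise ValueError(f"ref must be a single base, got {self.ref!r}")
        if self.alt not in "ACGT" or len(self.alt) != 1:
            raise ValueError(f"alt must be a single base, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref})")
        for label, f in (("af_ea", self.af_ea), ("af_aa", self.af_aa)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{label} out of [0,1]: {f}")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class AlleleCountRecord:
    """Reference / alternate read counts at one heterozygous site."""

    variant_id: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass
class Pwm:
    """A position probability matrix (width x 4, columns in A,C,G,T order)."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.width < 4:
            raise ValueError(f"PWM width must be >= 4, got {self.width}")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {self.motif_id} has negative entries")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(
                f"PWM {self.motif_id} rows do not sum to 1 (max dev "
                f"{np.max(np.abs(sums - 1.0)):.2e})"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1])


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def _check_alphabet(seq: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot(seq: str) -> np.ndarray:
    """Encode a DNA string as an L x 4 matrix (columns A,C,G,T; N -> 0.25)."""
    seq = seq.upper()
    _check_alphabet(seq)
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros((256, 4), dtype=np.float32)
    for i, b in enumerate(BASE_ORDER):
        lut[ord(b), i] = 1.0
    lut[ord("N")] = 0.25
    return lut[idx]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}.

    Record order is preserved (dicts are ordered).  Sequence names are the
    first whitespace-separated token of the header.
    """
    path = Path(path)
    out: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].strip() else None
                if name is None:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunk = line.upper()
                _check_alphabet(chunk)
                chunks.append(chunk)
    if name is None:
        raise FormatError(f"{path}: no FASTA records found")
    out[name] = "".join(chunks)
    return out


def write_fasta(path: str | Path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file; column 4 (if present) becomes the interval name."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) <= start ({start})"
                )
            name = fields[3] if len(fields) > 3 else None
            intervals.append(GenomicInterval(chrom, start, end, name))
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# variant tables (minimal sites-only VCF, or TSV)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "af_ea", "af_aa"]


def _parse_info(info: str) -> dict[str, str]:
    out = {}
    for item in info.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_variant_table(
    path: str | Path, dialect: Literal["vcf", "tsv"] = "tsv"
) -> list[VariantRecord]:
    """Read biallelic SNVs from a minimal sites-only VCF or a TSV.

    VCF: positions are 1-based; INFO must carry AF_EA and AF_AA.  TSV: header
    columns id, chrom, pos (1-based), ref, alt, af_ea, af_aa.  Multi-allelic
    and indel records are skipped (count logged); per-record validation errors
    are collected and raised together.
    """
    path = Path(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    errors: list[str] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: fewer than 8 VCF columns")
            chrom, pos_s, vid, ref, alt = fields[:5]
            info = _parse_info(fields[7])
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            if "AF_EA" not in info or "AF_AA" not in info:
                errors.append(f"{path}:{lineno}: missing AF_EA/AF_AA INFO key")
                continue
            try:
                records.append(
                    VariantRecord(
                        id=vid if vid != "." else f"{chrom}:{pos_s}",
                        chrom=chrom,
                        pos=int(pos_s) - 1,
                        ref=ref.upper(),
                        alt=alt.upper(),
                        af_ea=float(info["AF_EA"]),
                        af_aa=float(info["AF_AA"]),
                    )
                )
            except ValueError as exc:
                errors.append(f"{path}:{lineno}: {exc}")
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel records in %s", n_skipped, path)
    if errors:
        raise FormatError(
            f"{len(errors)} invalid variant records:\n" + "\n".join(errors)
        )
    return records


def _read_variant_tsv(path: Path) -> list[VariantRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[VariantRecord] = []
    errors: list[str] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1:
            n_skipped += 1
            continue
        try:
            records.append(
                VariantRecord(
                    id=str(row.id),
                    chrom=str(row.chrom),
                    pos=int(row.pos) - 1,
                    ref=ref,
                    alt=alt,
                    af_ea=float(row.af_ea),
                    af_aa=float(row.af_aa),
                )
            )
        except ValueError as exc:
            errors.append(f"{path} id={row.id}: {exc}")
    if n_skipped:
        logger.info("skipped %d non-SNV records in %s", n_skipped, path)
    if errors:
        raise FormatError(
            f"{len(errors)} invalid variant records:\n" + "\n".join(errors)
        )
    return records


def write_variant_tsv(path: str | Path, variants: Iterable[VariantRecord]) -> None:
    """Write variants as TSV with 1-based positions (round-trips read_variant_table)."""
    import pandas as pd

    rows = [
        {
            "id": v.id,
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "ref": v.ref,
            "alt": v.alt,
            "af_ea": v.af_ea,
            "af_aa": v.af_aa,
            "fst": "" if v.fst is None else v.fst,
            "dominance": "" if v.dominance is None else v.dominance,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS + ["fst", "dominance"]).to_csv(
        path, sep="\t", index=False
    )


def write_vcf(path: str | Path, variants: Iterable[VariantRecord]) -> None:
    """Write a minimal sites-only VCF with AF_EA/AF_AA INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF_EA,Number=1,Type=Float,Description="Alt AF, EA panel">\n')
        fh.write('##INFO=<ID=AF_AA,Number=1,Type=Float,Description="Alt AF, AA panel">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t"
                f"AF_EA={v.af_ea:.6g};AF_AA={v.af_aa:.6g}\n"
            )


# ---------------------------------------------------------------------------
# allele count TSV
# ---------------------------------------------------------------------------

def read_allele_counts(path: str | Path) -> list[AlleleCountRecord]:
    """Read a TSV with columns variant_id, ref_reads, alt_reads."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in ("variant_id", "ref_reads", "alt_reads") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        AlleleCountRecord(str(r.variant_id), int(r.ref_reads), int(r.alt_reads))
        for r in df.itertuples(index=False)
    ]


def write_allele_counts(path: str | Path, counts: Iterable[AlleleCountRecord]) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"variant_id": c.variant_id, "ref_reads": c.ref_reads, "alt_reads": c.alt_reads}
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme(path: str | Path) -> list[Pwm]:
    """Read MEME minimal-format motifs; rows off stochastic by <= 1e-3 are renormalized.

    The letter-probability matrices are parsed directly at full precision
    (Bio.motifs' minimal reader quantizes probabilities to nsites-scaled
    integer counts, which would corrupt low-probability PWM entries).
    """
    path = Path(path)
    pwms: list[Pwm] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{i + 1}: MOTIF line without a name")
            name = parts[1]
            # advance to the letter-probability header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(
                        f"{path}: motif {name}: no letter-probability matrix"
                    )
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name}: no letter-probability matrix")
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}:{i + 1}: motif {name}: expected 4 probabilities"
                    )
                rows.append([float(v) for v in vals])
                i += 1
            matrix = np.array(rows, dtype=float)
            sums = matrix.sum(axis=1)
            dev = np.abs(sums - 1.0)
            if np.any(dev > 1e-3):
                raise FormatError(
                    f"{path}: motif {name}: probability row sums deviate from 1 "
                    f"by up to {dev.max():.3g} (> 1e-3)"
                )
            pwms.append(Pwm(name, matrix / sums[:, None]))
        else:
            i += 1
    if not pwms:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return pwms


def write_meme(path: str | Path, pwms: Iterable[Pwm]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
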