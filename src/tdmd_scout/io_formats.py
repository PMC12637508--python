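"""Readers/writers for the external formats the pipeline touches.

All stages share the small set of frozen record types defined here.
Coordinates in machine output are 0-based half-open on the transcript sense
strand; miRNA positions in pairing strings are 1-based from the 5' end.
DNA input is accepted and normalized to RNA (T -> U); mixed or foreign
alphabets are rejected with the offending line number.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
GAPPED_ALPHABET = frozenset("ACGUN-")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class FormatError(ValueError):
    """Malformed input file (bad FASTA/MAF/TSV structure or alphabet)."""


class SchemaError(ValueError):
    """A table is missing required columns or fails type coercion."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (5'->3' in, 5'->3' out)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


_GAPPED_COMPLEMENT_MAP = str.maketrans("ACGUN-", "UGCAN-")


def reverse_complement_gapped(seq: str) -> str:
    """Reverse complement preserving gap and N columns (for MAF rows)."""
    return seq.translate(_GAPPED_COMPLEMENT_MAP)[::-1]


def normalize_rna(seq: str, *, dna_to_rna: bool = True) -> str:
    seq = seq.upper()
    if dna_to_rna:
        seq = seq.replace("T", "U")
    return seq


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'->3' over {A,C,G,U}.

    ``normalization_partners`` lists co-transcribed miRNAs (cluster members or
    the passenger strand) used as references when isolating degradation
    effects from transcription/processing variability.
    """

    mirna_id: str
    sequence: str
    species: str = ""
    cluster_id: str | None = None
    normalization_partners: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 16 <= len(self.sequence) <= 30:
            raise ValueError(
                f"{self.mirna_id}: mature miRNA length {len(self.sequence)} "
                "outside [16, 30]"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.mirna_id}: non-RNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def nt(self, pos: int) -> str:
        """Base at 1-based position ``pos`` from the 5' end."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"miRNA position {pos} outside 1..{len(self.sequence)}")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class TranscriptRegion:
    """A 3' UTR or lncRNA sequence (sense strand) with gene-level TPM."""

    transcript_id: str
    gene_id: str
    region_kind: str  # {"UTR3", "lncRNA"}
    sequence: str
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.region_kind not in ("UTR3", "lncRNA"):
            raise ValueError(f"region_kind {self.region_kind!r} not UTR3/lncRNA")
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if self.tpm < 0:
            raise ValueError(f"{self.transcript_id}: negative TPM {self.tpm}")

    def with_tpm(self, tpm: float) -> "TranscriptRegion":
        return replace(self, tpm=tpm)


@dataclass(frozen=True)
class AlignmentBlock:
    """One MAF alignment paragraph in reference orientation.

    ``rows`` maps species name to its gapped row; minus-strand rows have been
    reverse-complemented at read time so all rows read along the reference
    sense strand.
    """

    reference_species: str
    rows: Mapping[str, str]
    reference_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError("alignment rows of unequal length")
        if self.reference_species not in self.rows:
            raise FormatError(
                f"reference species {self.reference_species!r} absent from block"
            )

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_species]

    @property
    def reference_length(self) -> int:
        return sum(1 for c in self.reference_row if c != "-")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, encoding="ascii")


def read_fasta(path: str | Path, alphabet_policy: str = "dna_to_rna") -> list[tuple[str, str]]:
    """Parse a FASTA file into ``[(id, RNA sequence), ...]``.

    ``alphabet_policy`` is ``"rna"`` (reject T) or ``"dna_to_rna"`` (T -> U).
    IDs are the first whitespace-delimited header token.  Violations raise
    :class:`FormatError` naming the line number.
    """
    if alphabet_policy not in ("rna", "dna_to_rna"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    allowed = RNA_ALPHABET if alphabet_policy == "rna" else RNA_ALPHABET | {"T"}
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is not None:
            records.append(
                (current_id, normalize_rna("".join(chunks), dna_to_rna=True))
            )

    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                upper = line.upper()
                bad = set(upper) - allowed
                if bad:
                    raise FormatError(
                        f"{path}: disallowed character(s) {sorted(bad)} "
                        f"at line {lineno}"
                    )
                chunks.append(upper)
    flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="ascii") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_mirna_fasta(
    path: str | Path,
    partners: Mapping[str, Sequence[str]] | None = None,
    species: str = "",
) -> list[MatureMiRNA]:
    """Read mature miRNAs from FASTA, attaching normalization partners."""
    partners = partners or {}
    seen: set[str] = set()
    out = []
    for name, seq in read_fasta(path):
        if name in seen:
            raise FormatError(f"{path}: duplicate miRNA id {name!r}")
        seen.add(name)
        out.append(
            MatureMiRNA(
                mirna_id=name,
                sequence=seq,
                species=species,
                normalization_partners=tuple(partners.get(name, ())),
            )
        )
    return out


def read_maf(path: str | Path, reference_species: str | None = None) -> list[AlignmentBlock]:
    """Parse a MAF file into :class:`AlignmentBlock` objects (file order).

    The reference species is the first ``s`` row of each block unless given
    explicitly.  Rows recorded on the minus strand are reverse-complemented
    into reference orientation.  Lowercase (soft-masked) bases are upper-cased
    and T is normalized to U.
    """
    blocks: list[AlignmentBlock] = []
    current: list[tuple[str, int, str, str]] | None = None  # (species, start, strand, text)

    def flush(block_index: int) -> None:
        nonlocal current
        if current is None:
            return
        if not current:
            current = None
            return
        ref_species = reference_species or current[0][0]
        rows: dict[str, str] = {}
        ref_start = None
        lengths = set()
        for species, start, strand, text in current:
            text = normalize_rna(text, dna_to_rna=True)
            if strand == "-":
                text = reverse_complement_gapped(text)
            lengths.add(len(text))
            rows[species] = text
            if species == ref_species:
                ref_start = start
        if len(lengths) > 1:
            raise FormatError(f"MAF block {block_index}: rows of unequal length")
        if ref_species not in rows:
            raise FormatError(
                f"MAF block {block_index}: missing reference species {ref_species!r}"
            )
        blocks.append(
            AlignmentBlock(
                reference_species=ref_species,
                rows=rows,
                reference_start=ref_start if ref_start is not None else 0,
            )
        )
        current = None

    with _open_text(path) as handle:
        block_index = 0
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("a"):
                flush(block_index)
                block_index += 1
                current = []
            elif line.startswith("s"):
                if current is None:
                    raise FormatError(f"{path}: 's' line outside block at line {lineno}")
                parts = line.split()
                if len(parts) < 7:
                    raise FormatError(f"{path}: short 's' line at line {lineno}")
                _, src, start, _size, strand, _srcsize, text = parts[:7]
                species = src.split(".")[0]
                current.append((species, int(start), strand, text))
            # "i"/"e"/"q" annotation lines and comments are ignored
        flush(block_index)
    return blocks


EXPRESSION_SCHEMA = {"gene_id": str, "sample_id": str, "tpm": float}

CONSERVED_SITE_SCHEMA = {
    "mirna_id": str,
    "transcript_id": str,
    "seed_start": int,
    "seed_end": int,
    "site_type": str,
}

DE_SCHEMA = {"mirna_id": str, "log2fc": float, "padj": float}

GENE_DE_SCHEMA = {"gene_id": str, "log2fc": float}


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a header-ed TSV, coercing columns per ``schema``.

    Extra columns are preserved as strings.  Missing required columns raise
    :class:`SchemaError` listing their names; a negative ``tpm`` raises a
    validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, typ in schema.items():
        if typ is not str:
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}: column {col!r} not coercible to "
                                  f"{typ.__name__}: {exc}") from exc
    if "tpm" in schema and (df["tpm"] < 0).any():
        bad = df.loc[df["tpm"] < 0].index[0]
        raise SchemaError(f"{path}: negative TPM at data row {bad}")
    return df


CANDIDATE_COLUMNS = [
    "mirna_id", "transcript_id", "gene_id", "site_type", "seed_start",
    "seed_end", "score", "base_points", "end_bonus", "terminal_wobble_bonus",
    "interruption_penalty", "offset_penalty", "offset",
    "duplex_energy_kcal_mol", "tpm", "rank", "pairing_string",
]


def candidates_to_frame(candidates: Sequence) -> pd.DataFrame:
    """Flatten TriggerCandidate objects into the fixed-column table."""
    rows = []
    for c in candidates:
        b = c.best_config.breakdown
        rows.append({
            "mirna_id": c.mirna_id,
            "transcript_id": c.match.transcript_id,
            "gene_id": c.gene_id,
            "site_type": c.match.site_type,
            "seed_start": c.match.seed_start,
            "seed_end": c.match.seed_end,
            "score": c.best_config.total_score,
            "base_points": b.base_points,
            "end_bonus": b.end_bonus,
            "terminal_wobble_bonus": b.terminal_wobble_bonus,
            "interruption_penalty": b.interruption_penalty,
            "offset_penalty": b.offset_penalty,
            "offset": c.best_config.offset if c.best_config.pairs else 0,
            "duplex_energy_kcal_mol": (
                "" if c.duplex_energy is None else f"{c.duplex_energy:.2f}"
            ),
            "tpm": c.tpm,
            "rank": c.rank,
            "pairing_string": c.pairing_oneline,
        })
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return df.sort_values(["mirna_id", "rank", "transcript_id"], kind="mergesort").reset_index(drop=True)


def write_candidates(candidates: Sequence, path: str | Path) -> None:
    """Write ranked candidates as a TSV with the documented column order."""
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> pd.DataFrame:
    schema = {
        "mirna_id": str, "transcript_id": str, "gene_id": str,
        "site_type": str, "seed_start": int, "seed_end": int, "score": float,
        "base_points": float, "end_bonus": float,
        "terminal_wobble_bonus": float, "interruption_penalty": float,
        "offset_penalty": float, "offset": int, "tpm": float, "rank": int,
    }
    df = read_table(path, schema)
    return df
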