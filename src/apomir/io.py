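"""Core data model and readers/writers for every external format in the pipeline.

The pipeline works with four kinds of external data:

* expression matrices (TSV; rows = features, columns = samples) — raw mRNA
  counts, miRNA array intensities, normalized expression, or per-subject
  differential expression;
* per-sample metadata (CSV) describing the paired tumor/normal design and
  the survival follow-up;
* sequences (FASTA) — mature miRNAs (RNA alphabet) and gene 3'UTRs (DNA);
* pathway gene lists (one identifier per line).

Matrix columns are linked to metadata through the ``<subject>_T`` /
``<subject>_N`` sample-id convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Structural problem with an input file (bad header, duplicate ids...)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a domain invariant."""


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Site(str, enum.Enum):
    COLON = "colon"
    RECTAL = "rectal"


class Phenotype(str, enum.Enum):
    MSS = "MSS"
    MSI = "MSI"
    UNKNOWN = "unknown"


class Vital(str, enum.Enum):
    DEAD = "dead"
    ALIVE = "alive"


class MatrixKind(str, enum.Enum):
    MRNA_COUNTS = "mrna_counts"
    MIRNA_INTENSITY = "mirna_intensity"
    RPMPCG = "rpmpcg"
    DIFFERENTIAL = "differential"


@dataclass(frozen=True)
class SampleMeta:
    """One tissue sample of one subject, with subject-level covariates.

    Survival fields describe the subject (shared by the tumor and normal
    record): months from diagnosis to death or last contact, vital status,
    and whether colorectal cancer was listed as a primary or secondary
    cause of death (``crc_death``) — the event indicator for
    disease-specific survival.
    """

    subject_id: str
    tissue: Tissue
    age: float
    sex: Sex
    site: Site
    stage: int
    phenotype: Phenotype
    vital: Vital
    survival_months: float
    crc_death: bool

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be nonempty")
        if self.stage not in (1, 2, 3, 4):
            raise ValidationError(
                f"subject {self.subject_id!r}: AJCC stage must be 1-4, got {self.stage}"
            )
        if not (self.survival_months >= 0):
            raise ValidationError(
                f"subject {self.subject_id!r}: survival_months must be >= 0, "
                f"got {self.survival_months}"
            )
        if self.age <= 0:
            raise ValidationError(f"subject {self.subject_id!r}: age must be positive")

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_{'T' if self.tissue is Tissue.TUMOR else 'N'}"


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with a declared kind.

    ``values`` is a pandas DataFrame indexed by feature id with sample-id
    columns. Counts (``mrna_counts``) must be nonnegative integers; all
    other kinds are nonnegative reals except ``differential``, which may be
    negative (tumor minus normal).
    """

    values: pd.DataFrame
    kind: MatrixKind

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_f = idx[idx.duplicated()].unique().tolist()
        if dup_f:
            raise FormatError(f"duplicate feature ids: {dup_f}")
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise FormatError(f"duplicate sample ids: {dup_s}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing expression value at feature {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.kind is not MatrixKind.DIFFERENTIAL and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at feature {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.kind is MatrixKind.MRNA_COUNTS:
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at feature {idx[i]!r}, sample {cols[j]!r}"
                )
            self.values = self.values.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PathwayGeneList:
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError("pathway gene list is empty")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValidationError(f"duplicate gene id in pathway list: {g!r}")
            seen.add(g)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


_DNA = set("ACGTN")
_RNA = set("ACGUN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence; DNA for 3'UTRs, RNA for mature miRNAs."""

    id: str
    seq: str
    alphabet: str = "dna"  # "dna" | "rna"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        allowed = _DNA if self.alphabet == "dna" else _RNA
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in allowed:
                raise ValidationError(
                    f"sequence {self.id!r}: character {ch!r} at position {pos} "
                    f"not in {self.alphabet.upper()} alphabet"
                )

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path, kind: MatrixKind | str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature id, header of sample ids)."""
    kind = MatrixKind(kind)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV; integer counts verbatim, reals with fixed 10-digit precision."""
    df = matrix.values
    if matrix.kind is MatrixKind.MRNA_COUNTS:
        df.to_csv(path, sep="\t", index_label="feature")
    else:
        df.to_csv(path, sep="\t", index_label="feature", float_format="%.10g")


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read FASTA records in file order, upper-cased, validated against the alphabet."""
    if alphabet not in ("dna", "rna"):
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), alphabet))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def read_pathway_gene_list(path: str | Path) -> PathwayGeneList:
    """Read a one-id-per-line gene list; blank lines and '#' comments skipped."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return PathwayGeneList(tuple(ids))


def write_pathway_gene_list(genes: PathwayGeneList, path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))


_META_COLUMNS = [
    "subject_id",
    "tissue",
    "age",
    "sex",
    "site",
    "stage",
    "phenotype",
    "vital",
    "survival_months",
    "crc_death",
]


def _parse_enum(cls, token: str, row: str, col: str):
    try:
        return cls(token)
    except ValueError:
        raise ValidationError(
            f"row {row!r}: unknown {col} value {token!r} "
            f"(allowed: {[e.value for e in cls]})"
        ) from None


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the per-sample metadata CSV.

    Every SampleMeta column is required. The phenotype cell may be empty
    (recorded as ``unknown``); every other field must be present. The
    tumor/normal pairing invariant is *not* enforced here — call
    :func:`check_pairing` when a paired analysis needs it.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata file missing required columns: {missing}")
    out = []
    for _, r in df.iterrows():
        sid = r["subject_id"]
        pheno = r["phenotype"].strip()
        try:
            stage = int(r["stage"])
        except ValueError:
            raise ValidationError(f"row {sid!r}: stage must be an integer 1-4") from None
        crc = r["crc_death"].strip().lower()
        if crc not in ("true", "false", "0", "1"):
            raise ValidationError(f"row {sid!r}: crc_death must be boolean, got {crc!r}")
        out.append(
            SampleMeta(
                subject_id=sid,
                tissue=_parse_enum(Tissue, r["tissue"], sid, "tissue"),
                age=float(r["age"]),
                sex=_parse_enum(Sex, r["sex"], sid, "sex"),
                site=_parse_enum(Site, r["site"], sid, "site"),
                stage=stage,
                phenotype=Phenotype.UNKNOWN
                if pheno == ""
                else _parse_enum(Phenotype, pheno, sid, "phenotype"),
                vital=_parse_enum(Vital, r["vital"], sid, "vital"),
                survival_months=float(r["survival_months"]),
                crc_death=crc in ("true", "1"),
            )
        )
    return out


def write_sample_meta(meta: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "subject_id": m.subject_id,
                "tissue": m.tissue.value,
                "age": f"{m.age:.10g}",
                "sex": m.sex.value,
                "site": m.site.value,
                "stage": m.stage,
                "phenotype": "" if m.phenotype is Phenotype.UNKNOWN else m.phenotype.value,
                "vital": m.vital.value,
                "survival_months": f"{m.survival_months:.10g}",
                "crc_death": str(m.crc_death).lower(),
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def check_pairing(meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    """Verify each subject has exactly one tumor and one normal record.

    Returns a map subject_id -> tumor record (a convenient subject-level
    view). Raises :class:`ValidationError` listing every offending subject.
    """
    by_subject: dict[str, dict[Tissue, int]] = {}
    tumor_rec: dict[str, SampleMeta] = {}
    for m in meta:
        d = by_subject.setdefault(m.subject_id, {Tissue.TUMOR: 0, Tissue.NORMAL: 0})
        d[m.tissue] += 1
        if m.tissue is Tissue.TUMOR:
            tumor_rec[m.subject_id] = m
    bad = sorted(
        s
        for s, d in by_subject.items()
        if d[Tissue.TUMOR] != 1 or d[Tissue.NORMAL] != 1
    )
    if bad:
        raise ValidationError(f"subjects without exactly one tumor + one normal record: {bad}")
    return tumor_rec


def subjects_of(meta: Sequence[SampleMeta]) -> list[str]:
    """Unique subject ids in first-appearance order."""
    seen: dict[str, None] = {}
    for m in meta:
        seen.setdefault(m.subject_id, None)
    return list(seen)
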