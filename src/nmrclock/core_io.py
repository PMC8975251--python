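"""Domain types and on-disk formats.

Containers wrap pandas objects and validate the invariants a methylation
study must satisfy (beta values in [0, 1], unique identifiers, paired
sample ordering). On-disk formats are plain text:

* BetaMatrix — CSV/TSV, rows = CpGs, columns = samples, top-left header
  cell ``cpg_id`` (or ``sample_id`` for the transposed orientation; the
  sentinel is how orientation is auto-detected). Missing betas are empty
  fields.
* SampleSheet — CSV with one row per sample.
* CpGManifest — BED-like TSV: chrom, 0-based start, half-open end,
  cpg_id, gene, signed TSS distance (negative = upstream), region class,
  island flag, comma-separated species-mappability labels.
* ClockModel — JSON (transform spec, intercept, sparse coefficients,
  training medians and metadata); serialization round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agetx import TransformSpec

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "SampleSheet",
    "CpGManifest",
    "ClockModel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_manifest",
    "write_manifest",
    "align",
]

SEXES = ("F", "M", "unknown")
BREEDING_STATUSES = ("queen", "breeder_male", "nonbreeder", "unknown")
CELL_TYPES = ("tissue", "fibroblast", "iPSC")
REGION_CLASSES = ("promoter", "5'UTR", "exon", "intron", "3'UTR", "distal")


class ValidationError(ValueError):
    """Input violates a domain invariant (maps to CLI exit code 2)."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """Samples x CpGs methylation fractions.

    ``values`` is a float DataFrame with sample ids as the index and CpG
    ids as columns. NaN encodes a missing measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "cpg ids")
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"({self.values.index[r]}, {self.values.columns[c]})={arr[r, c]:g}"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(f"beta values outside [0,1] at {cells}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleSheet:
    """Per-sample metadata: age, tissue, sex, species, breeding status."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "age_years", "tissue", "sex", "species", "breeding_status")

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns {missing}")
        if "cell_type" not in df.columns:
            df["cell_type"] = "tissue"
        _check_unique(df["sample_id"], "sample ids")
        df["age_years"] = df["age_years"].astype(float)
        if (df["age_years"] < 0).any():
            bad = df.loc[df["age_years"] < 0, "sample_id"].tolist()[:5]
            raise ValidationError(f"negative age_years for samples {bad}")
        for col, allowed in (
            ("sex", SEXES),
            ("breeding_status", BREEDING_STATUSES),
            ("cell_type", CELL_TYPES),
        ):
            bad = set(df[col]) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} values {sorted(bad)}; allowed {allowed}")
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CpGManifest:
    """BED-like per-CpG annotation (0-based half-open coordinates)."""

    frame: pd.DataFrame

    REQUIRED = (
        "cpg_id",
        "chrom",
        "start",
        "end",
        "gene",
        "signed_tss_distance",
        "region_class",
        "island_flag",
        "species_mappable",
    )

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns {missing}")
        _check_unique(df["cpg_id"], "cpg ids")
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] < 0).any():
            raise ValidationError("manifest start coordinates must be >= 0")
        df["island_flag"] = df["island_flag"].astype(bool)
        bad = set(df["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValidationError(f"invalid region_class values {sorted(bad)}")
        self.frame = df

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.frame["cpg_id"])

    def mappable_mask(self, species: str) -> np.ndarray:
        """Boolean mask over manifest rows: probe maps to ``species``."""
        col = self.frame["species_mappable"]
        return np.array(
            [species in (s if isinstance(s, (set, list, tuple)) else str(s).split(",")) for s in col]
        )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ClockModel:
    """A fitted penalized-regression epigenetic clock.

    intercept is on the transformed-age scale; coefficients is the
    sparse map of nonzero CpG weights. training_medians stores per-CpG
    medians of the training betas for imputing missing values at
    prediction time.
    """

    transform: TransformSpec
    intercept: float
    coefficients: dict[str, float]
    training_medians: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "transform": self.transform.to_dict(),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "training_medians": self.training_medians,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        d = json.loads(Path(path).read_text())
        return cls(
            transform=TransformSpec.from_dict(d["transform"]),
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            training_medians=d["training_medians"],
            metadata=d.get("metadata", {}),
        )


# ---------------------------------------------------------------------
# readers / writers


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValidationError(f"unknown dialect {dialect!r}")
        return "," if dialect == "csv" else "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".bed", ".txt") else ","


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    out = matrix.values.T.rename_axis("cpg_id")  # rows = CpGs on disk
    out.to_csv(path, sep=sep, float_format="%.10g", na_rep="")


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    sentinel = (df.index.name or "").strip().lower()
    if sentinel == "cpg_id":
        df = df.T  # -> samples x cpgs
    elif sentinel != "sample_id":
        raise ValidationError(
            f"cannot detect orientation of {path}: header sentinel must be 'cpg_id' or 'sample_id', got {df.index.name!r}"
        )
    df.index.name = None
    df.columns.name = None
    return BetaMatrix(df.astype(float))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


_MANIFEST_COLS = list(CpGManifest.REQUIRED)
_BED_ORDER = [
    "chrom",
    "start",
    "end",
    "cpg_id",
    "gene",
    "signed_tss_distance",
    "region_class",
    "island_flag",
    "species_mappable",
]


def write_manifest(manifest: CpGManifest, path: str | Path) -> None:
    df = manifest.frame.copy()
    df["species_mappable"] = [
        ",".join(sorted(s)) if isinstance(s, (set, list, tuple)) else str(s)
        for s in df["species_mappable"]
    ]
    df["island_flag"] = df["island_flag"].astype(int)
    df[_BED_ORDER].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> CpGManifest:
    df = pd.read_csv(path, sep="\t")
    df["island_flag"] = df["island_flag"].astype(bool)
    return CpGManifest(df)


# ---------------------------------------------------------------------


def align(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    manifest: CpGManifest,
    species: str | None = None,
) -> tuple[BetaMatrix, SampleSheet, CpGManifest, dict]:
    """Restrict and reorder a study triple to its common ids.

    Samples are ordered as in the matrix; CpGs are restricted to the
    manifest intersection and, when ``species`` is given, to probes
    mappable to that species. Returns the aligned triple plus a report
    of the counts dropped at each step.
    """
    common_samples = [s for s in matrix.sample_ids if s in set(sheet.sample_ids)]
    if not common_samples:
        raise ValidationError("no samples shared between matrix and sample sheet")

    man = manifest.frame
    if species is not None:
        man = man[manifest.mappable_mask(species)]
    keep_cpgs = [c for c in matrix.cpg_ids if c in set(man["cpg_id"])]
    if not keep_cpgs:
        raise ValidationError("no CpGs shared between matrix and manifest after mappability filter")

    report = {
        "samples_dropped_from_matrix": matrix.n_samples - len(common_samples),
        "samples_dropped_from_sheet": len(sheet) - len(common_samples),
        "cpgs_dropped_unmappable": matrix.n_cpgs - len(keep_cpgs),
    }

    values = matrix.values.loc[common_samples, keep_cpgs]
    sheet_out = SampleSheet(
        sheet.frame.set_index("sample_id").loc[common_samples].reset_index()
    )
    man_out = CpGManifest(man.set_index("cpg_id").loc[keep_cpgs].reset_index())
    return BetaMatrix(values), sheet_out, man_out, report
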