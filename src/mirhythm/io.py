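"""Readers and writers for the tabular formats the pipeline consumes.

All matrices and design tables travel as tab-separated text; the
miRTarBase-style target table and the pathway table are comma-separated,
matching how those upstream resources are distributed.  Every reader
validates the invariants of its table (non-negative expression, unique
identifiers, consistent arm labels, ...) and raises a structured error
naming the offending cell or column rather than propagating a pandas
exception.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MetadataError",
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "read_targets",
    "read_pathways",
    "normalize_mirna_id",
]

#: recognised species prefixes on miRNA identifiers (rat, human, mouse)
_SPECIES_PREFIX = re.compile(r"^(rno|hsa|mmu)-")


class FormatError(ValueError):
    """A file violates the declared table format or an invariant."""


class MetadataError(ValueError):
    """Expression samples and the metadata table disagree."""


def normalize_mirna_id(mirna_id: str, strip_species_prefix: bool = False) -> str:
    """Whitespace-strip an identifier; optionally drop an rno-/hsa-/mmu- prefix.

    Rat miRNAs are mapped onto human identifiers for target lookup, so the
    prefix is preserved by default and stripped only on request.
    """
    out = mirna_id.strip()
    if strip_species_prefix:
        out = _SPECIES_PREFIX.sub("", out)
    return out


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Features x samples matrix of non-negative normalized expression.

    ``data`` rows are features, columns are samples.  The expression unit is
    carried as free-text metadata (``unit``); the pipeline accepts any
    non-negative normalized unit and never rescales on read.
    """

    data: pd.DataFrame
    unit: str = "r.u."

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"missing or non-finite value at feature {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        neg = values < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise FormatError(
                f"negative expression {values[r, c]} at feature "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def feature(self, feature_id: str) -> np.ndarray:
        """Expression of one feature in sample-column order."""
        return self.data.loc[feature_id].to_numpy(dtype=float)


def read_expression(path, metadata: pd.DataFrame) -> ExpressionMatrix:
    """Read a TSV expression matrix and align its columns to *metadata* order.

    First column = feature id, header = sample ids.  Every sample in the
    header must appear in ``metadata['sample_id']``; columns are reordered to
    follow the metadata so that downstream time vectors align positionally.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    meta_samples = list(metadata["sample_id"].astype(str))
    unknown = [s for s in df.columns if s not in meta_samples]
    if unknown:
        raise MetadataError(
            f"samples present in {path} but absent from metadata: {unknown}"
        )
    ordered = [s for s in meta_samples if s in df.columns]
    return ExpressionMatrix(df.loc[:, ordered])


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV at 6 significant digits (round-trip precision)."""
    matrix.data.to_csv(path, sep="\t", float_format="%.6g", index_label="feature_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (sample_id, zt_hours, replicate[, group]).

    ZT is hours since lights-on; values in [0, 36) are allowed so that a
    single run spanning the dark->light transition (e.g. ZT26, ZT30) keeps
    monotone clock times.
    """
    required = {"sample_id", "zt_hours", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing required columns: {sorted(missing)}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    zt = meta["zt_hours"].to_numpy(dtype=float)
    if not np.isfinite(zt).all():
        raise FormatError("non-finite zt_hours in metadata")
    if (zt < 0).any() or (zt >= 36).any():
        raise FormatError("zt_hours outside the allowed range [0, 36)")
    rep = meta["replicate"].to_numpy()
    if (rep != np.floor(rep)).any() or (rep < 1).any():
        raise FormatError("replicate must be a positive integer")
    if "group" not in meta.columns:
        meta["group"] = ""
    return meta


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# arm / precursor / locus annotation
# ---------------------------------------------------------------------------


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate the mature-arm -> precursor -> locus linkage table."""
    required = {"mature_id", "arm", "precursor_id", "locus_id"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"annotation missing required columns: {sorted(missing)}")
    ann = ann.copy()
    for col in required:
        ann[col] = ann[col].astype(str).str.strip()
    bad_arm = ~ann["arm"].isin(["5p", "3p"])
    if bad_arm.any():
        raise FormatError(
            f"arm must be 5p or 3p, got {sorted(ann.loc[bad_arm, 'arm'].unique())}"
        )
    key = ann[["mature_id", "precursor_id", "locus_id"]]
    if key.duplicated().any():
        raise FormatError("duplicate (mature_id, precursor_id, locus_id) triples")
    arms_per_mature = ann.groupby("mature_id")["arm"].nunique()
    inconsistent = arms_per_mature[arms_per_mature > 1]
    if len(inconsistent):
        raise FormatError(
            f"inconsistent arm label for mature ids: {list(inconsistent.index)}"
        )
    return ann


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# target interactions (miRTarBase-style CSV)
# ---------------------------------------------------------------------------

_TARGET_ALIASES = {
    "mirna_id": ("mirna_id", "mirna", "miRNA"),
    "target_gene": ("target_gene", "target gene", "Target Gene", "gene"),
    "support_type": ("support_type", "support type", "Support Type"),
    "species": ("species", "Species (miRNA)", "species (mirna)"),
}


def _resolve_column(df: pd.DataFrame, canonical: str, required: bool = True):
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for alias in _TARGET_ALIASES[canonical]:
        if alias.lower() in lowered:
            return lowered[alias.lower()]
    if required:
        raise FormatError(
            f"target table is missing a column for {canonical!r} "
            f"(accepted headers: {_TARGET_ALIASES[canonical]})"
        )
    return None


def read_targets(path, evidence_filter: set[str] | None = None) -> pd.DataFrame:
    """Read a miRTarBase-like CSV of validated miRNA:target interactions.

    ``evidence_filter`` keeps only rows whose support type is in the given
    label set (e.g. ``{"Functional MTI"}`` for strong evidence); ``None``
    keeps everything.  Duplicate interactions are collapsed.
    """
    df = pd.read_csv(path)
    cols = {
        "mirna_id": _resolve_column(df, "mirna_id"),
        "target_gene": _resolve_column(df, "target_gene"),
        "support_type": _resolve_column(df, "support_type"),
    }
    species_col = _resolve_column(df, "species", required=False)
    out = pd.DataFrame(
        {
            "mirna_id": df[cols["mirna_id"]].astype(str).str.strip(),
            "target_gene": df[cols["target_gene"]].astype(str).str.strip(),
            "support_type": df[cols["support_type"]].astype(str).str.strip(),
            "species": (
                df[species_col].astype(str).str.strip() if species_col else ""
            ),
        }
    )
    if (out["target_gene"] == "").any() or out["target_gene"].isin(["nan"]).any():
        raise FormatError("empty target gene symbol in target table")
    if evidence_filter is not None:
        out = out[out["support_type"].isin(set(evidence_filter))]
    out = out.drop_duplicates().reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# gene -> pathway table (Panther-style accessions)
# ---------------------------------------------------------------------------


def read_pathways(path) -> pd.DataFrame:
    """Read a CSV of (gene_symbol, pathway_accession, pathway_name) rows."""
    df = pd.read_csv(path)
    required = {"gene_symbol", "pathway_accession", "pathway_name"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"pathway table missing columns: {sorted(missing)}")
    df = df.copy()
    for col in required:
        df[col] = df[col].astype(str).str.strip()
    if (df["pathway_accession"] == "").any():
        raise FormatError("empty pathway accession")
    df = df.drop_duplicates(subset=["gene_symbol", "pathway_accession"])
    return df.reset_index(drop=True)
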