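"""Readers, writers and validated in-memory containers for every table the
pipeline touches.

All interchange is delimited text (TSV by default, CSV accepted).  Missing
beta values are accepted as empty string or ``NA`` on read and written back
as ``NA``.  Genomic coordinates follow the Illumina 450K manifest
convention: 1-based, position is the interrogated CpG's cytosine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "PairManifest",
    "SampleCovariates",
    "ProbeAnnotation",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_pair_manifest",
    "write_pair_manifest",
    "read_sample_covariates",
    "write_sample_covariates",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_probe_scores",
    "write_results_table",
    "read_results_table",
    "genomic_sort_key",
]

MISSING_TOKENS = ["", "NA"]

ZYGOSITIES = ("MZ", "DZ")
SEXES = ("F", "M")
SMOKING_LEVELS = ("current", "former", "never")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
GENE_FEATURES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")

MANIFEST_COLUMNS = ["pair_id", "sample_id_a", "sample_id_b", "zygosity", "sex", "family_id"]

RESULTS_COLUMNS = [
    "probe_id", "chrom", "position", "n_MZ", "n_DZ", "r_MZ", "r_DZ",
    "A", "C", "E", "A_raw", "C_raw", "E_raw", "loglik", "converged",
    "boundary", "method",
]

# Illumina HumanMethylation450 manifest column names -> internal names
ILLUMINA_COLUMN_MAP = {
    "IlmnID": "probe_id",
    "CHR": "chrom",
    "MAPINFO": "position",
    "Strand": "strand",
    "UCSC_RefGene_Group": "gene_features",
    "Relation_to_UCSC_CpG_Island": "island_relation",
}


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class BetaMatrix:
    """Sites x individuals methylation proportions in [0, 1], NaN = missing."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        bad = np.where((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value out of [0, 1] at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        return self.probe_ids.index(probe_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        idx = [self.probe_ids.index(p) for p in probe_ids]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return BetaMatrix(list(self.probe_ids), list(sample_ids), self.values[:, idx])

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.values[:, [pos[s] for s in sample_ids]]


@dataclass
class PairManifest:
    """Twin-pair structure: one row per same-sex pair, MZ or DZ."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in f.columns]
        if missing:
            raise ValidationError(f"pair manifest missing columns: {missing}")
        f = f[MANIFEST_COLUMNS].astype(str).reset_index(drop=True)
        bad_zyg = sorted(set(f["zygosity"]) - set(ZYGOSITIES))
        if bad_zyg:
            raise ValidationError(f"unknown zygosity code(s): {bad_zyg}")
        bad_sex = sorted(set(f["sex"]) - set(SEXES))
        if bad_sex:
            raise ValidationError(f"unknown sex code(s): {bad_sex}")
        _check_unique(list(f["pair_id"]), "pair id")
        members = list(f["sample_id_a"]) + list(f["sample_id_b"])
        _check_unique(members, "sample id (listed in more than one pair slot)")
        self.frame = f

    @property
    def n_mz(self) -> int:
        return int((self.frame["zygosity"] == "MZ").sum())

    @property
    def n_dz(self) -> int:
        return int((self.frame["zygosity"] == "DZ").sum())

    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id_a"]) + list(self.frame["sample_id_b"])

    def pairs(self, zygosity: str | None = None, sex: str | None = None) -> pd.DataFrame:
        f = self.frame
        if zygosity is not None:
            f = f[f["zygosity"] == zygosity]
        if sex is not None:
            f = f[f["sex"] == sex]
        return f

    def missing_from(self, betas: BetaMatrix) -> list[str]:
        """Sample ids present in the manifest but absent from a beta matrix.

        Flagged, never dropped silently: the caller decides what to do.
        """
        have = set(betas.sample_ids)
        return [s for s in self.sample_ids() if s not in have]


@dataclass
class SampleCovariates:
    """Per-sample covariates keyed by sample id.

    Recognized columns: ``smoking_status`` ({current, former, never}),
    ``batch`` (categorical), any number of cell-proportion columns (prefix
    ``cell_``, each in [0, 1]) and arbitrary continuous phenotype columns
    (e.g. ``DNAmAge``).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.copy()
        if f.index.name != "sample_id":
            if "sample_id" in f.columns:
                f = f.set_index("sample_id")
            else:
                f.index.name = "sample_id"
        f.index = f.index.astype(str)
        _check_unique(list(f.index), "sample id")
        if "smoking_status" in f.columns:
            levels = set(f["smoking_status"].dropna().astype(str))
            bad = sorted(levels - set(SMOKING_LEVELS))
            if bad:
                raise ValidationError(f"unknown smoking_status level(s): {bad}")
        for col in f.columns:
            if col.startswith("cell_"):
                v = pd.to_numeric(f[col], errors="coerce")
                out = v[(v < 0) | (v > 1)]
                if len(out):
                    raise ValidationError(
                        f"cell proportion outside [0, 1] in column {col!r} "
                        f"for sample {out.index[0]!r}"
                    )
        self.frame = f

    def for_samples(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"covariates missing for samples: {missing[:5]}")
        return self.frame.loc[list(sample_ids)]


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation plus optional external scores.

    ``gene_features`` is a ``;``-joined subset of the 450K feature
    vocabulary; ``island_relation`` is exactly one of Island/Shore/Shelf/
    OpenSea.  ``tss_distance`` is strand-aware signed bp (negative =
    upstream).  Any further numeric columns (mQTL effect, cross-tissue
    covariation r, chromatin state label) ride along in the frame.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.copy()
        if f.index.name != "probe_id":
            if "probe_id" in f.columns:
                f = f.set_index("probe_id")
            else:
                f.index.name = "probe_id"
        f.index = f.index.astype(str)
        _check_unique(list(f.index), "probe id")
        for col in ("chrom", "position"):
            if col not in f.columns:
                raise ValidationError(f"probe annotation missing column {col!r}")
        f["chrom"] = f["chrom"].astype(str)
        if (f["chrom"] == "").any():
            raise ValidationError("empty chrom in probe annotation")
        f["position"] = pd.to_numeric(f["position"]).astype(int)
        if (f["position"] < 1).any():
            bad = f.index[f["position"] < 1][0]
            raise ValidationError(f"position < 1 for probe {bad!r}")
        if "island_relation" in f.columns:
            rel = set(f["island_relation"].dropna().astype(str))
            bad = sorted(rel - set(ISLAND_RELATIONS))
            if bad:
                raise ValidationError(f"unknown island_relation value(s): {bad}")
        self.frame = f

    def chrom_of(self) -> pd.Series:
        return self.frame["chrom"]

    def scores(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise ValidationError(f"no per-probe score column {name!r}")
        return pd.to_numeric(self.frame[name], errors="coerce")


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    """Read a probes-by-samples beta table (first column = probe id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0,
                     na_values=MISSING_TOKENS, keep_default_na=False, dtype=str)
    values = df.astype(float).to_numpy(dtype=float)  # correctly rounded parse
    return BetaMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_beta_matrix(betas: BetaMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    betas.to_frame().to_csv(path, sep=_sep_for(path, dialect), na_rep="NA",
                            index_label="probe_id")


def read_pair_manifest(path: str | Path, dialect: str | None = None) -> PairManifest:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str,
                     na_values=[], keep_default_na=False)
    return PairManifest(df)


def write_pair_manifest(manifest: PairManifest, path: str | Path,
                        dialect: str | None = None) -> None:
    path = Path(path)
    manifest.frame.to_csv(path, sep=_sep_for(path, dialect), index=False)


def read_sample_covariates(path: str | Path, dialect: str | None = None) -> SampleCovariates:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), na_values=MISSING_TOKENS,
                     keep_default_na=False)
    return SampleCovariates(df)


def write_sample_covariates(cov: SampleCovariates, path: str | Path,
                            dialect: str | None = None) -> None:
    path = Path(path)
    cov.frame.to_csv(path, sep=_sep_for(path, dialect), na_rep="NA",
                     index_label="sample_id")


def _map_island_relation(raw: str) -> str:
    raw = str(raw)
    if raw in ("", "nan", "NA"):
        return "OpenSea"
    if "Shore" in raw:
        return "Shore"
    if "Shelf" in raw:
        return "Shelf"
    if raw == "Island":
        return "Island"
    return raw  # validated downstream


def read_probe_annotation(path: str | Path, dialect: str | None = None) -> ProbeAnnotation:
    """Read probe annotation, accepting either internal or Illumina 450K
    manifest column names (IlmnID, CHR, MAPINFO, UCSC_RefGene_Group,
    Relation_to_UCSC_CpG_Island)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str,
                     na_values=MISSING_TOKENS, keep_default_na=False)
    renames = {k: v for k, v in ILLUMINA_COLUMN_MAP.items() if k in df.columns}
    df = df.rename(columns=renames)
    if "island_relation" in df.columns:
        df["island_relation"] = df["island_relation"].map(_map_island_relation)
    if "gene_features" in df.columns:
        # Illumina lists one entry per transcript; deduplicate, keep order
        def _dedup(s: object) -> str:
            parts = [p for p in str(s).split(";") if p and p != "nan"]
            seen: list[str] = []
            for p in parts:
                if p not in seen:
                    seen.append(p)
            return ";".join(seen) if seen else "intergenic"
        df["gene_features"] = df["gene_features"].map(_dedup)
    for col in ("tss_distance",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in df.columns:
        if col not in ("probe_id", "chrom", "strand", "gene_features",
                       "island_relation", "chromatin_state"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path,
                           dialect: str | None = None) -> None:
    path = Path(path)
    ann.frame.to_csv(path, sep=_sep_for(path, dialect), na_rep="NA",
                     index_label="probe_id")


def read_probe_scores(path: str | Path, column: str | None = None,
                      dialect: str | None = None) -> pd.Series:
    """Read a two-column probe_id -> value table (mQTL flag/effect,
    covariation r, ...)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), na_values=MISSING_TOKENS,
                     keep_default_na=False)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    col = column if column is not None else df.columns[0]
    return pd.to_numeric(df[col], errors="coerce")


_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def genomic_sort_key(chrom: str) -> tuple[int, float, str]:
    """Natural chromosome order: 1..22 numerically, then X, Y, MT, others."""
    body = _CHROM_RE.match(str(chrom)).group(2)
    if body.isdigit():
        return (0, int(body), "")
    special = {"X": 0, "Y": 1, "MT": 2, "M": 2}
    if body.upper() in special:
        return (1, special[body.upper()], "")
    return (2, 0, body)


def _fmt6(x: object) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{float(x):.6g}"


def write_results_table(rows: Iterable, path: str | Path,
                        annotation: ProbeAnnotation | None = None) -> None:
    """Write VarianceDecomposition records as a deterministic TSV.

    Rows are genomically sorted (natural chrom order, then position, then
    probe id); floats carry 6 significant digits.  Coordinates come from
    the record itself or, failing that, from ``annotation``.
    """
    path = Path(path)
    recs = []
    for r in rows:
        chrom = getattr(r, "chrom", None)
        pos = getattr(r, "position", None)
        if (chrom is None or pos is None) and annotation is not None:
            if r.name in annotation.frame.index:
                row = annotation.frame.loc[r.name]
                chrom = str(row["chrom"])
                pos = int(row["position"])
        recs.append({
            "probe_id": r.name,
            "chrom": "NA" if chrom is None else str(chrom),
            "position": 0 if pos is None else int(pos),
            "n_MZ": "NA" if r.n_mz is None else int(r.n_mz),
            "n_DZ": "NA" if r.n_dz is None else int(r.n_dz),
            "r_MZ": _fmt6(r.r_mz),
            "r_DZ": _fmt6(r.r_dz),
            "A": _fmt6(r.A),
            "C": _fmt6(r.C),
            "E": _fmt6(r.E),
            "A_raw": _fmt6(r.a2),
            "C_raw": _fmt6(r.c2),
            "E_raw": _fmt6(r.e2),
            "loglik": _fmt6(r.loglik),
            "converged": str(bool(r.converged)),
            "boundary": ";".join(sorted(r.boundary)) if r.boundary else ".",
            "method": r.method,
        })
    recs.sort(key=lambda d: (genomic_sort_key(d["chrom"]), d["position"], d["probe_id"]))
    out = pd.DataFrame(recs, columns=RESULTS_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=MISSING_TOKENS, keep_default_na=False)
    for col in ("r_MZ", "r_DZ", "A", "C", "E", "A_raw", "C_raw", "E_raw", "loglik"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
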