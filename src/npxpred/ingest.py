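"""Reading, QC, imputation and standardisation of NPX proteomics matrices.

NPX (Normalised Protein Expression) is a log2-scale relative
quantification unit: values are comparable within one protein assay but
not across proteins, so every protein is scaled to a standard normal
before modelling.  Proteins are identified as ``NAME:PANEL`` because the
same protein may be assayed on two panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NpxDataset",
    "ClinicalTable",
    "ReferenceStats",
    "read_npx",
    "read_clinical",
    "apply_qc",
    "mask_below_lod",
    "impute_knn",
    "standardize",
    "standardize_new",
]


def _read_table(path) -> pd.DataFrame:
    """CSV/TSV with auto-detected delimiter, UTF-8, first row header."""
    try:
        return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValueError(f"could not parse {path}: {exc}") from exc


@dataclass
class NpxDataset:
    """Samples x proteins NPX matrix with LoD, QC flags and missing mask."""

    sample_ids: list[str]
    protein_ids: list[str]  # "NAME:PANEL"
    values: np.ndarray  # float (n_samples, n_proteins)
    lod: np.ndarray  # float (n_proteins,)
    panels: list[str]  # panel label per protein
    qc_flag: pd.DataFrame = field(default=None)  # bool, samples x panels
    missing_mask: np.ndarray = field(default=None)  # bool, same shape as values

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lod = np.asarray(self.lod, dtype=float)
        n, p = len(self.sample_ids), len(self.protein_ids)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} != ({n}, {p})"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.protein_ids)) != p:
            raise ValueError("duplicate protein ids")
        if self.lod.shape != (p,):
            raise ValueError("lod must have one value per protein")
        if len(self.panels) != p:
            raise ValueError("panels must have one label per protein")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")
            self.missing_mask = self.missing_mask | ~np.isfinite(self.values)
        if self.qc_flag is None:
            self.qc_flag = pd.DataFrame(
                False,
                index=list(self.sample_ids),
                columns=sorted(set(self.panels)),
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.protein_ids)

    def copy(self) -> "NpxDataset":
        return replace(
            self,
            values=self.values.copy(),
            lod=self.lod.copy(),
            missing_mask=self.missing_mask.copy(),
            qc_flag=self.qc_flag.copy(),
        )


@dataclass
class ClinicalTable:
    """Per-patient demographics and response labels (M=1/F=0; R=1/NR=0)."""

    frame: pd.DataFrame

    REQUIRED = (
        "patient_id",
        "gender",
        "age",
        "disease_duration",
        "baseline_das",
        "delta_das",
        "response",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.frame["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids")
        das = self.frame["baseline_das"]
        if ((das < 0) | (das > 10)).any():
            raise ValueError("baseline_das outside [0, 10]")
        if not self.frame["response"].isin([0, 1]).all():
            raise ValueError("response must be 0/1")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame["patient_id"])

    @property
    def response(self) -> np.ndarray:
        return self.frame["response"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ReferenceStats:
    """Per-feature mean/SD of a reference cohort, used to z-score new input."""

    feature_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_cohort: int

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in reference stats")
        if not (np.asarray(self.sd) > 0).all():
            raise ValueError("reference SDs must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_ids, "mean": self.mean, "sd": self.sd}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_cohort: int = 0) -> "ReferenceStats":
        return cls(
            feature_ids=tuple(frame["feature"]),
            mean=frame["mean"].to_numpy(dtype=float),
            sd=frame["sd"].to_numpy(dtype=float),
            n_cohort=n_cohort,
        )


def _strip(s) -> str:
    return str(s).strip()


def read_npx(path, layout: str = "wide", lod_path=None, qc_path=None) -> NpxDataset:
    """Read an NPX table.

    ``wide``: first column sample id, remaining columns protein ids
    (``NAME:PANEL``); LoD and QC come from companion files with columns
    (protein, lod) and (sample, panel, flag).

    ``long``: columns sample_id, protein, panel, npx, lod, qc_warning;
    duplicate (sample, protein, panel) rows are an error.
    """
    if layout == "wide":
        df = _read_table(path)
        sample_ids = [_strip(s) for s in df.iloc[:, 0]]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"{path}: repeated sample id")
        protein_ids = [_strip(c) for c in df.columns[1:]]
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        panels = [p.rsplit(":", 1)[1] if ":" in p else "NA" for p in protein_ids]
        if lod_path is not None:
            lod_df = _read_table(lod_path)
            lod_map = dict(
                zip((_strip(x) for x in lod_df.iloc[:, 0]), lod_df.iloc[:, 1])
            )
            missing = [p for p in protein_ids if p not in lod_map]
            if missing:
                raise ValueError(f"LoD missing for proteins: {missing[:5]}")
            lod = np.array([float(lod_map[p]) for p in protein_ids])
        else:
            lod = np.full(len(protein_ids), np.nan)
        qc = None
        if qc_path is not None:
            qc_df = _read_table(qc_path)
            qc_df.columns = [c.lower() for c in qc_df.columns]
            qc = pd.DataFrame(
                False, index=sample_ids, columns=sorted(set(panels))
            )
            for _, row in qc_df.iterrows():
                s, pnl = _strip(row.iloc[0]), _strip(row.iloc[1])
                if s in qc.index and pnl in qc.columns:
                    qc.loc[s, pnl] = bool(int(row.iloc[2]))
        return NpxDataset(sample_ids, protein_ids, values, lod, panels, qc_flag=qc)

    if layout == "long":
        df = _read_table(path)
        needed = {"sample_id", "protein", "panel", "npx", "lod", "qc_warning"}
        if not needed.issubset(df.columns):
            raise ValueError(
                f"{path}: long layout needs columns {sorted(needed)}"
            )
        df = df.assign(
            sample_id=df["sample_id"].map(_strip),
            protein=df["protein"].map(_strip),
            panel=df["panel"].map(_strip),
        )
        key = df[["sample_id", "protein", "panel"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"{path}: duplicate row for sample={dup['sample_id']} "
                f"protein={dup['protein']} panel={dup['panel']}"
            )
        df["pid"] = df["protein"] + ":" + df["panel"]
        wide = df.pivot(index="sample_id", columns="pid", values="npx")
        sample_ids = [str(s) for s in wide.index]
        protein_ids = [str(p) for p in wide.columns]
        panels = [p.rsplit(":", 1)[1] for p in protein_ids]
        lod_map = df.groupby("pid")["lod"].first()
        lod = lod_map.loc[protein_ids].to_numpy(dtype=float)
        qc = (
            df.groupby(["sample_id", "panel"])["qc_warning"]
            .max()
            .unstack(fill_value=0)
            .astype(bool)
        )
        qc = qc.reindex(index=sample_ids).fillna(False)
        return NpxDataset(
            sample_ids, protein_ids, wide.to_numpy(dtype=float), lod, panels,
            qc_flag=qc,
        )

    raise ValueError(f"unknown layout {layout!r}; use 'wide' or 'long'")


def read_clinical(path) -> ClinicalTable:
    """Clinical CSV/TSV with gender given as M/F and response as R/NR."""
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if df["gender"].dtype == object:
        df["gender"] = df["gender"].str.strip().str.upper().map({"M": 1, "F": 0})
    if df["response"].dtype == object:
        df["response"] = (
            df["response"].str.strip().str.upper().map({"R": 1, "NR": 0})
        )
    df["patient_id"] = df["patient_id"].map(_strip)
    return ClinicalTable(df)


def write_npx(ds: NpxDataset, npx_path, lod_path=None, qc_path=None) -> None:
    """Write the wide NPX CSV and its companion LoD / QC files."""
    ds.to_frame().rename_axis("sample_id").to_csv(npx_path)
    if lod_path is not None:
        pd.DataFrame({"protein": ds.protein_ids, "lod": ds.lod}).to_csv(
            lod_path, index=False
        )
    if qc_path is not None:
        rows = [
            {"sample": s, "panel": pnl, "flag": int(ds.qc_flag.loc[s, pnl])}
            for s in ds.sample_ids
            for pnl in ds.qc_flag.columns
        ]
        pd.DataFrame(rows).to_csv(qc_path, index=False)


def apply_qc(ds: NpxDataset) -> NpxDataset:
    """Mask every cell of a (sample, panel) pair carrying a QC warning."""
    out = ds.copy()
    panel_arr = np.array(ds.panels)
    for s_idx, sample in enumerate(ds.sample_ids):
        for panel in ds.qc_flag.columns:
            if bool(ds.qc_flag.loc[sample, panel]):
                out.missing_mask[s_idx, panel_arr == panel] = True
    return out


def mask_below_lod(ds: NpxDataset) -> NpxDataset:
    """Mask cells strictly below the protein's limit of detection.

    Values exactly equal to the LoD are retained.
    """
    if not np.isfinite(ds.lod).all():
        bad = [ds.protein_ids[i] for i in np.flatnonzero(~np.isfinite(ds.lod))]
        raise ValueError(f"missing/non-finite LoD for proteins: {bad[:5]}")
    out = ds.copy()
    with np.errstate(invalid="ignore"):
        below = ds.values < ds.lod[None, :]
    out.missing_mask |= below
    return out


def impute_knn(
    ds: NpxDataset, k: int = 5, *, max_missing_fraction: float = 0.10
) -> NpxDataset:
    """k-nearest-neighbour imputation.

    The imputed value is the unweighted mean of the k nearest samples'
    values for that protein; distances are Euclidean over mutually
    observed proteins, and only donors observing the protein qualify.
    """
    n, p = ds.shape
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    frac = ds.missing_fraction
    if frac > max_missing_fraction:
        raise ValueError(
            f"missing fraction {frac:.3f} exceeds ceiling {max_missing_fraction}"
        )
    obs = ~ds.missing_mask
    if (~obs).all(axis=1).any():
        bad = [ds.sample_ids[i] for i in np.flatnonzero((~obs).all(axis=1))]
        raise ValueError(f"samples with all proteins missing: {bad}")
    vals = ds.values.copy()
    vals[ds.missing_mask] = np.nan
    out = ds.copy()
    rows, cols = np.nonzero(ds.missing_mask)
    # squared Euclidean over mutually observed proteins, per sample pair
    for i in np.unique(rows):
        shared = obs & obs[i]  # (n, p) mutual observation with sample i
        diff = np.where(shared, vals - vals[i], 0.0)
        d2 = np.einsum("ij,ij->i", diff, diff)
        n_shared = shared.sum(axis=1)
        d2 = np.where(n_shared > 0, d2, np.inf)
        d2[i] = np.inf
        for j in cols[rows == i]:
            donors = np.flatnonzero(obs[:, j] & np.isfinite(d2))
            if donors.size == 0:
                raise ValueError(
                    f"no donor for sample {ds.sample_ids[i]}, "
                    f"protein {ds.protein_ids[j]}"
                )
            nearest = donors[np.argsort(d2[donors], kind="stable")[:k]]
            out.values[i, j] = vals[nearest, j].mean()
            out.missing_mask[i, j] = False
    if out.missing_mask.any():  # pragma: no cover - defensive
        raise RuntimeError("imputation left missing cells")
    return out


def standardize(ds: NpxDataset) -> tuple[pd.DataFrame, ReferenceStats]:
    """Scale each protein column to mean 0, sample SD 1.

    Requires a complete matrix; returns the z-matrix and the pre-scaling
    per-protein mean/SD as :class:`ReferenceStats`.
    """
    if ds.missing_mask.any():
        raise ValueError("standardize requires a complete matrix; impute first")
    mean = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        names = [ds.protein_ids[i] for i in zero]
        raise ValueError(f"zero-variance proteins: {names}")
    z = (ds.values - mean) / sd
    ref = ReferenceStats(
        feature_ids=tuple(ds.protein_ids),
        mean=mean,
        sd=sd,
        n_cohort=len(ds.sample_ids),
    )
    return pd.DataFrame(z, index=ds.sample_ids, columns=ds.protein_ids), ref


def standardize_new(record: dict, ref: ReferenceStats) -> np.ndarray:
    """z-score a new record against reference cohort statistics.

    Every reference feature must be present; unknown extras are ignored
    with a warning.
    """
    missing = [f for f in ref.feature_ids if f not in record]
    if missing:
        raise ValueError(f"record missing features: {missing}")
    extra = [f for f in record if f not in ref.feature_ids]
    if extra:
        warnings.warn(f"ignoring unknown features: {extra}", stacklevel=2)
    x = np.array([float(record[f]) for f in ref.feature_ids])
    return (x - ref.mean) / ref.sd
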