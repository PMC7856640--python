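"""Containers and derived features for multimodal imaging feature tables.

The analysis operates on *structure-level* features: one row per subject, one
column per anatomical feature.  Four modalities are supported:

- ``volume`` — regional volumes from T1-weighted segmentation (mm^3),
- ``FA`` — regional mean fractional anisotropy (unitless, in [0, 1]),
- ``MD`` — regional mean diffusivity (mm^2/s),
- ``rsfmri`` — Fisher z-transformed pairwise resting-state correlations
  between seed regions.

Everything upstream of these tables (segmentation, registration, tensor
fitting, nuisance regression) is out of scope; the package begins at the
feature-table level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MODALITIES = ("volume", "FA", "MD", "rsfmri")

#: Groups: healthy controls, schizophrenia-spectrum first-episode psychosis,
#: mood-disorder-with-psychotic-features first-episode psychosis.
GROUPS = ("HC", "S_FEP", "M_FEP")


class DataModelError(ValueError):
    """Raised on malformed feature tables or invariant violations."""


@dataclass
class FeatureBlock:
    """One modality's subjects-by-features matrix.

    Parameters
    ----------
    modality : str
        One of :data:`MODALITIES`.
    values : ndarray, shape (n_subjects, n_features)
        Complete (no missing entries) numeric matrix.
    feature_names : list of str
        Unique column labels, length ``n_features``.
    subject_ids : list of str
        Unique row labels, length ``n_subjects``.
    """

    modality: str
    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    #: True once values are centered/scaled (raw-scale range checks no longer apply)
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DataModelError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataModelError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise DataModelError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise DataModelError("feature names must be unique")
        if len(self.subject_ids) != n:
            raise DataModelError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(set(self.subject_ids)) != n:
            raise DataModelError("duplicate subject IDs")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataModelError(
                f"missing/non-finite value at subject {self.subject_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r} (complete-case design)"
            )
        if self.modality == "FA" and not self.standardized and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise DataModelError("FA values must lie in [0, 1]")
        if self.modality == "rsfmri":
            for name in self.feature_names:
                a, _, b = name.partition("__")
                if not b or not a < b:
                    raise DataModelError(
                        f"rsfmri feature {name!r} is not a canonical 'A__B' pair "
                        "with A < B"
                    )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class CovariateDesign:
    """Encoded covariate matrix aligned with the feature blocks.

    ``Y`` holds the numeric design used by the factor model (group dummies
    with HC as reference, z-scored age, binary sex, race codes); the original
    group label per subject is kept alongside for stratified operations.
    """

    Y: np.ndarray
    column_names: list[str]
    group_labels: np.ndarray  # array of str, values in GROUPS
    subject_ids: list[str]
    encoding_spec: dict = field(default_factory=dict)
    #: subject subsets may legitimately zero a rare dummy column
    allow_zero_columns: bool = False

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        n, q = self.Y.shape
        if len(self.column_names) != q:
            raise DataModelError("column_names length must match Y columns")
        if len(self.group_labels) != n or len(self.subject_ids) != n:
            raise DataModelError("covariate rows must align with subjects")
        if q and not np.all(np.isfinite(self.Y)):
            raise DataModelError("non-finite covariate entries")
        if not self.allow_zero_columns:
            for j in range(q):
                col = self.Y[:, j]
                if np.all(col == 0):
                    raise DataModelError(
                        f"covariate column {self.column_names[j]!r} is constant zero"
                    )

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.Y.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        if group not in set(self.group_labels):
            raise DataModelError(f"unknown group label {group!r}")
        return np.flatnonzero(self.group_labels == group)

    def subset(self, idx: np.ndarray) -> "CovariateDesign":
        idx = np.asarray(idx)
        return CovariateDesign(
            Y=self.Y[idx],
            column_names=list(self.column_names),
            group_labels=self.group_labels[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            encoding_spec=dict(self.encoding_spec),
            allow_zero_columns=True,
        )


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters over time for one fMRI run.

    Columns 0..2 are translations in mm, columns 3..5 rotations in radians
    (degree inputs must be converted on read).
    """

    params: np.ndarray  # (n_timepoints, 6)

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise DataModelError("motion trace must have six columns")
        if self.params.shape[0] < 2:
            raise DataModelError("motion trace needs at least 2 time points")
        if not np.all(np.isfinite(self.params)):
            raise DataModelError("non-finite motion parameters")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]


@dataclass
class MultiModalDataset:
    """Aligned feature blocks plus covariates for ``n`` subjects."""

    blocks: list[FeatureBlock]
    covariates: CovariateDesign
    standardization: dict | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DataModelError("need at least one feature block")
        ids = self.blocks[0].subject_ids
        for blk in self.blocks[1:]:
            if blk.subject_ids != ids:
                raise DataModelError(
                    "all blocks must share identical subject_ids in order"
                )
        if self.covariates.subject_ids != ids:
            raise DataModelError("covariates must align with block subjects")

    @property
    def n_subjects(self) -> int:
        return self.blocks[0].n_subjects

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_dims(self) -> list[int]:
        return [b.n_features for b in self.blocks]

    @property
    def subject_ids(self) -> list[str]:
        return self.blocks[0].subject_ids

    def block(self, modality: str) -> FeatureBlock:
        for b in self.blocks:
            if b.modality == modality:
                return b
        raise DataModelError(f"no block with modality {modality!r}")

    def matrices(self) -> list[np.ndarray]:
        return [b.values for b in self.blocks]

    def concatenated(self) -> np.ndarray:
        return np.hstack(self.matrices())

    def subset(self, idx: np.ndarray) -> "MultiModalDataset":
        """Row-subset (and possibly reorder/repeat, e.g. bootstrap) subjects."""
        idx = np.asarray(idx)
        new_ids = [f"{self.subject_ids[i]}#{j}" for j, i in enumerate(idx)]
        blocks = [
            FeatureBlock(
                b.modality, b.values[idx], list(b.feature_names), new_ids,
                standardized=b.standardized,
            )
            for b in self.blocks
        ]
        cov = self.covariates.subset(idx)
        cov.subject_ids = new_ids
        return MultiModalDataset(blocks, cov, self.standardization)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, modality: str, standardized: bool = False) -> FeatureBlock:
    """Read a delimited feature table (header = feature names, first column
    ``subject_id``) into a validated :class:`FeatureBlock`.

    Pass ``standardized=True`` for tables already on a centered/scaled scale
    (raw-range checks are then skipped).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise DataModelError(f"{path}: expected subject_id column plus features")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise DataModelError(f"{path}: duplicated subject row")
    feat = df.iloc[:, 1:]
    for col in feat.columns:
        vals = pd.to_numeric(feat[col], errors="coerce")
        bad = vals.isna() & feat[col].notna()
        if bad.any():
            row = ids[int(np.flatnonzero(bad)[0])]
            raise DataModelError(
                f"{path}: non-numeric cell at subject {row!r}, column {col!r}"
            )
        if vals.isna().any():
            row = ids[int(np.flatnonzero(vals.isna())[0])]
            raise DataModelError(
                f"{path}: missing value at subject {row!r}, column {col!r}"
            )
        feat[col] = vals
    return FeatureBlock(
        modality=modality,
        values=feat.to_numpy(dtype=float),
        feature_names=[str(c) for c in feat.columns],
        subject_ids=ids,
        standardized=standardized,
    )


def write_feature_table(block: FeatureBlock, path) -> None:
    """Write a block as CSV with 17 significant digits (bitwise round-trip)."""
    block.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_covariate_table(path) -> pd.DataFrame:
    """Read the raw demographics CSV (subject_id, group, age, sex, race)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "group", "age", "sex", "race"}
    missing = required - set(df.columns)
    if missing:
        raise DataModelError(f"{path}: missing covariate columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise DataModelError(f"{path}: duplicated subject_id")
    return df


def encode_covariates(
    demo: pd.DataFrame,
    group_dummies: tuple[str, ...] = ("S_FEP", "M_FEP"),
    collapse_rare_race: int = 5,
) -> CovariateDesign:
    """Encode demographics into the numeric design used by the factor model.

    HC is the reference group (all-zero dummies); age is z-scored; sex is
    binary (male=1); race levels rarer than ``collapse_rare_race`` subjects
    are collapsed into ``other`` before one-hot coding (dropping the most
    common level as reference).
    """
    demo = demo.reset_index(drop=True)
    bad = set(demo["group"]) - set(GROUPS)
    if bad:
        raise DataModelError(f"unknown group labels {sorted(bad)}")
    cols, names = [], []
    for g in group_dummies:
        cols.append((demo["group"] == g).to_numpy(float))
        names.append(f"group_{g}")
    age = demo["age"].to_numpy(float)
    age_mean, age_sd = float(age.mean()), float(age.std(ddof=1))
    cols.append((age - age_mean) / age_sd)
    names.append("age_z")
    cols.append((demo["sex"].astype(str) == "M").to_numpy(float))
    names.append("sex_male")
    race = demo["race"].astype(str).copy()
    counts = race.value_counts()
    race[race.map(counts) < collapse_rare_race] = "other"
    levels = race.value_counts().index.tolist()
    for lev in levels[1:]:  # most common level is the reference
        cols.append((race == lev).to_numpy(float))
        names.append(f"race_{lev}")
    Y = np.column_stack(cols) if cols else np.empty((len(demo), 0))
    return CovariateDesign(
        Y=Y,
        column_names=names,
        group_labels=demo["group"].to_numpy(object),
        subject_ids=demo["subject_id"].astype(str).tolist(),
        encoding_spec={
            "group_reference": "HC",
            "group_dummies": list(group_dummies),
            "age_mean": age_mean,
            "age_sd": age_sd,
            "sex_coding": {"M": 1, "F": 0},
            "race_reference": levels[0],
        },
    )


# ---------------------------------------------------------------------------
# Derived features
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Fisher z-transform z = atanh(r) = 0.5*ln((1+r)/(1-r)); requires |r|<1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise DataModelError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def pairwise_connectivity_features(
    corr: np.ndarray, seed_names: list[str], atol: float = 1e-8
) -> tuple[np.ndarray, list[str]]:
    """Vectorize the upper triangle of a seed correlation matrix as Fisher-z
    features with canonical unordered-pair names.

    For S seeds the result has S(S-1)/2 entries, in row-major upper-triangle
    order; names are ``"A__B"`` with A before B in the given seed order,
    swapped if needed so that A < B lexicographically.
    """
    corr = np.asarray(corr, dtype=float)
    S = corr.shape[0]
    if corr.shape != (S, S) or S < 2:
        raise DataModelError("correlation matrix must be square with S >= 2")
    if np.max(np.abs(corr - corr.T)) > atol:
        raise DataModelError("correlation matrix is asymmetric beyond tolerance")
    if np.max(np.abs(np.diag(corr) - 1.0)) > atol:
        raise DataModelError("correlation matrix must have unit diagonal")
    iu, ju = np.triu_indices(S, k=1)
    values = fisher_z(corr[iu, ju])
    names = []
    for i, j in zip(iu, ju):
        a, b = seed_names[i], seed_names[j]
        if not a < b:
            a, b = b, a
        names.append(f"{a}__{b}")
    return values, names


def framewise_displacement(
    trace: MotionTrace, sphere_radius: float = 50.0
) -> tuple[np.ndarray, float]:
    """Per-frame framewise displacement and its mean.

    FD_t = sum |Delta translation| + R * sum |Delta rotation| with rotations
    converted to arc length on a sphere of radius ``sphere_radius`` mm
    (50 mm by convention).  FD at the first frame is 0; the mean is taken
    over frames 2..T.
    """
    d = np.abs(np.diff(trace.params, axis=0))
    fd_rest = d[:, :3].sum(axis=1) + sphere_radius * d[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_rest])
    return fd, float(fd_rest.mean())


def qc_flag_subjects(
    fd_max: np.ndarray, max_fd: float = 0.5, fd_means: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Motion QC: include subjects whose maximum FD stays at or below
    ``max_fd`` mm; report summary statistics."""
    fd_max = np.asarray(fd_max, dtype=float)
    if not np.all(np.isfinite(fd_max)):
        raise DataModelError("non-finite FD values")
    mask = fd_max <= max_fd
    report = {
        "n_subjects": int(fd_max.size),
        "n_included": int(mask.sum()),
        "n_excluded": int((~mask).sum()),
        "max_fd_threshold_mm": float(max_fd),
    }
    if fd_means is not None:
        fd_means = np.asarray(fd_means, dtype=float)
        report["group_mean_fd_mm"] = float(fd_means.mean())
    return mask, report


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize_dataset(
    ds: MultiModalDataset, per_feature: bool = True
) -> MultiModalDataset:
    """Center every feature column (and scale to unit sample variance when
    ``per_feature``), recording the transform for inverse mapping.

    The Gaussian factor model mixes mm^3, mm^2/s and z-units; without
    per-feature scaling the largest-variance block dominates the likelihood.
    """
    if ds.n_subjects < 2:
        raise DataModelError("standardization needs n >= 2")
    record = {}
    new_blocks = []
    for blk in ds.blocks:
        center = blk.values.mean(axis=0)
        if per_feature:
            scale = blk.values.std(axis=0, ddof=1)
            # constant columns leave rounding residue of order eps*|center|
            zero = np.flatnonzero(scale <= 1e-12 * (1.0 + np.abs(center)))
            if zero.size:
                names = [blk.feature_names[i] for i in zero[:10]]
                raise DataModelError(
                    f"zero-variance features in {blk.modality}: {names}"
                )
        else:
            scale = np.ones_like(center)
        vals = (blk.values - center) / scale
        record[blk.modality] = {"center": center, "scale": scale}
        new_blocks.append(replace(blk, values=vals, standardized=True))
    return MultiModalDataset(new_blocks, ds.covariates, standardization=record)


def unstandardize_dataset(ds: MultiModalDataset) -> MultiModalDataset:
    """Invert :func:`standardize_dataset` using the stored record."""
    if ds.standardization is None:
        raise DataModelError("dataset carries no standardization record")
    blocks = []
    for blk in ds.blocks:
        rec = ds.standardization[blk.modality]
        blocks.append(
            replace(
                blk,
                values=blk.values * rec["scale"] + rec["center"],
                standardized=False,
            )
        )
    return MultiModalDataset(blocks, ds.covariates, standardization=None)


def apply_standardization(
    blocks: list[FeatureBlock], record: dict
) -> list[FeatureBlock]:
    """Standardize *new* subjects with a training-set record (no refitting)."""
    out = []
    for blk in blocks:
        rec = record[blk.modality]
        out.append(replace(blk, values=(blk.values - rec["center"]) / rec["scale"]))
    return out
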