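"""Cohort references and deviation features (sumdiff, MaxE, rmse).

Every B scan is scored against an average modulus spectrum built from eyes
other than its own: the cohort is sorted by axial length, each consecutive
block of five eyes is randomly spread over five groups (so the groups are
balanced on axial length), and the reference for a scan is the per-bin mean
spectrum over the B scans of the other four groups — i.e. 80% of the
cohort, never including the scored eye.  References are built per gaze
region ("regional" scope) or pooled over all regions ("all" scope).

Deviation of a scan from its reference over the 30 bins d_k = m_k - ref_k:

* ``sumdiff`` = sum_k |d_k|  (total absolute deviation, mm)
* ``MaxE``    = max_k |d_k|  (largest single-bin deviation, mm)
* ``rmse``    = sqrt(mean_k d_k^2)

so sumdiff >= MaxE >= rmse and sumdiff <= 30 MaxE for every scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as sio
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .descriptors import MODULUS_COLUMNS, N_BINS

ALL_SCOPE = "all"

FEATURES = ("sumdiff", "MaxE", "rmse")


class ReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class GroupAssignment:
    """Axial-length-balanced assignment of eyes to groups 1..n_groups."""

    groups: dict[str, int]
    n_groups: int
    seed: int

    def group_of(self, eye_id: str) -> int:
        return self.groups[eye_id]


def assign_groups(eyes: pd.Series | dict, n_groups: int = 5,
                  seed: int = 0) -> GroupAssignment:
    """Assign eyes to axial-length-balanced groups.

    ``eyes`` maps eye_id -> axial length (mm).  Eyes are sorted by axial
    length; each consecutive block of ``n_groups`` eyes is randomly
    permuted over the groups, and a remainder block of n < n_groups eyes is
    placed into n distinct random groups, so group sizes differ by at most
    one.  Deterministic for a given seed.
    """
    al = pd.Series(dict(eyes), dtype=float)
    if len(al) < n_groups:
        raise ReferenceError(
            f"need at least {n_groups} eyes to form {n_groups} groups, got {len(al)}"
        )
    order = al.sort_values(kind="mergesort").index  # eye_id tie-break via stable sort
    rng = np.random.default_rng(seed)
    groups: dict[str, int] = {}
    for start in range(0, len(order), n_groups):
        block = order[start:start + n_groups]
        chosen = rng.permutation(n_groups)[: len(block)] + 1
        for eye_id, g in zip(block, chosen):
            groups[str(eye_id)] = int(g)
    return GroupAssignment(groups=groups, n_groups=n_groups, seed=seed)


@dataclass(frozen=True)
class ReferenceProfile:
    """Average modulus spectrum for one (scope, held-out group) cell."""

    scope: str
    held_out_group: int
    mean_moduli: np.ndarray
    n_scans: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_moduli",
                           np.asarray(self.mean_moduli, dtype=float))
        if self.mean_moduli.shape != (N_BINS,):
            raise ReferenceError("reference must hold 30 bin means")
        if self.n_scans <= 0:
            raise ReferenceError("reference built from zero scans")


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ReferenceError(f"descriptor table missing columns: {sorted(missing)}")


def build_references(descriptors: pd.DataFrame, assignment: GroupAssignment,
                     scope_mode: str = "regional") -> dict[tuple[str, int], ReferenceProfile]:
    """Leave-one-group-out mean spectra per (scope, fold).

    ``scope_mode`` is ``"regional"`` (one reference per gaze region, built
    only from same-region scans) or ``"all"`` (one pooled reference).
    Every descriptor's eye must be assigned; an empty (scope, fold) cell is
    an error naming the cell.
    """
    if scope_mode not in ("regional", ALL_SCOPE):
        raise ReferenceError(f"scope_mode must be 'regional' or 'all', got {scope_mode!r}")
    _require_columns(descriptors, ("eye_id",) + MODULUS_COLUMNS)
    unassigned = set(descriptors["eye_id"].astype(str)) - set(assignment.groups)
    if unassigned:
        raise ReferenceError(f"eyes without a group assignment: {sorted(unassigned)}")

    df = descriptors.copy()
    df["_group"] = df["eye_id"].astype(str).map(assignment.groups)
    df["_scope"] = df["region"] if scope_mode == "regional" else ALL_SCOPE
    mods = list(MODULUS_COLUMNS)

    profiles: dict[tuple[str, int], ReferenceProfile] = {}
    empty: list[tuple[str, int]] = []
    for scope, scope_df in df.groupby("_scope", sort=True):
        for fold in range(1, assignment.n_groups + 1):
            keep = scope_df[scope_df["_group"] != fold]
            if keep.empty:
                empty.append((str(scope), fold))
                continue
            profiles[(str(scope), fold)] = ReferenceProfile(
                scope=str(scope), held_out_group=fold,
                mean_moduli=keep[mods].to_numpy(dtype=float).mean(axis=0),
                n_scans=len(keep),
            )
    if empty:
        raise ReferenceError(f"empty reference cells (scope, fold): {empty}")
    return profiles


@dataclass(frozen=True)
class ResidualFeatures:
    """Deviation of one scan's spectrum from its reference."""

    identity: tuple
    sumdiff: float
    MaxE: float
    rmse: float

    def __post_init__(self) -> None:
        eps = 1e-12 * max(1.0, self.sumdiff)
        if not (self.sumdiff + eps >= self.MaxE
                and self.MaxE + eps >= self.rmse >= 0
                and self.sumdiff <= N_BINS * self.MaxE + eps):
            raise ReferenceError(
                f"inconsistent residual features for {self.identity}: "
                f"{self.sumdiff}, {self.MaxE}, {self.rmse}"
            )


def residual_features(moduli: np.ndarray, ref: ReferenceProfile, *,
                      identity: tuple = (), region: str | None = None,
                      group: int | None = None) -> ResidualFeatures:
    """Score one scan's moduli against a reference profile.

    If ``region``/``group`` are supplied they are checked against the
    profile's scope and held-out group, preventing a scan from being scored
    against a reference that includes its own eye.
    """
    if group is not None and group != ref.held_out_group:
        raise ReferenceError(
            f"scan of group {group} scored against reference holding out "
            f"group {ref.held_out_group} (information leakage)"
        )
    if region is not None and ref.scope != ALL_SCOPE and ref.scope != region:
        raise ReferenceError(
            f"scan from region {region!r} scored against {ref.scope!r} reference"
        )
    moduli = np.asarray(moduli, dtype=float)
    if moduli.shape != (N_BINS,):
        raise ReferenceError("expected 30 bin moduli")
    d = np.abs(moduli - ref.mean_moduli)
    return ResidualFeatures(
        identity=identity,
        sumdiff=float(d.sum()),
        MaxE=float(d.max()),
        rmse=float(np.sqrt(np.mean(d * d))),
    )


FEATURE_COLUMNS = (
    "eye_id", "region", "cube_id", "scan_index", "axial_length_mm",
    "K", "sum_bins", "sumdiff", "MaxE", "rmse", "group", "scope",
)


def score_features(descriptors: pd.DataFrame, assignment: GroupAssignment,
                   references: dict[tuple[str, int], ReferenceProfile],
                   scope_mode: str = "regional") -> pd.DataFrame:
    """Scan-level sumdiff/MaxE/rmse against the fold-matched references."""
    _require_columns(descriptors, ("eye_id", "region") + MODULUS_COLUMNS)
    df = descriptors.copy()
    df["group"] = df["eye_id"].astype(str).map(assignment.groups)
    df["scope"] = df["region"] if scope_mode == "regional" else ALL_SCOPE
    mods = df[list(MODULUS_COLUMNS)].to_numpy(dtype=float)

    refs = np.empty_like(mods)
    for i, (scope, fold) in enumerate(zip(df["scope"], df["group"])):
        key = (str(scope), int(fold))
        if key not in references:
            raise ReferenceError(f"no reference for cell {key}")
        refs[i] = references[key].mean_moduli
    d = np.abs(mods - refs)
    out = df[["eye_id", "region", "cube_id", "scan_index",
              "axial_length_mm", "K", "sum_bins", "group", "scope"]].copy()
    out["sumdiff"] = d.sum(axis=1)
    out["MaxE"] = d.max(axis=1)
    out["rmse"] = np.sqrt((d * d).mean(axis=1))
    return out[list(FEATURE_COLUMNS)]


class LeaveGroupOutScorer(BaseEstimator, TransformerMixin):
    """Fit leave-group-out reference spectra; transform scans to features.

    Parameters
    ----------
    scope : "regional" or "all"
        Whether references are built per gaze region or pooled.
    n_groups : int
        Number of axial-length-balanced folds (five in the standard design).
    random_state : int
        Seed for the within-block random group assignment.

    ``fit`` expects a descriptor DataFrame (as produced by
    ``ContourShapeTransformer``) and records ``assignment_`` and
    ``references_``; ``transform`` returns the scan-level feature table.
    """

    def __init__(self, scope: str = "regional", n_groups: int = 5,
                 random_state: int = 0):
        self.scope = scope
        self.n_groups = n_groups
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        _require_columns(X, ("eye_id", "axial_length_mm") + MODULUS_COLUMNS)
        al = X.groupby(X["eye_id"].astype(str))["axial_length_mm"].first()
        self.assignment_ = assign_groups(al, n_groups=self.n_groups,
                                         seed=self.random_state)
        self.references_ = build_references(X, self.assignment_,
                                            scope_mode=self.scope)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "references_")
        return score_features(X, self.assignment_, self.references_,
                              scope_mode=self.scope)


SUMMARY_STATS = ("sumdiff", "MaxE", "rmse", "K")

_LEVEL_KEYS = {
    "eye": ["eye_id"],
    "region": ["region"],
    "eye_region": ["eye_id", "region"],
    "cube": ["eye_id", "region", "cube_id"],
}


def _iqr(v: np.ndarray) -> float:
    # linear interpolation between order statistics (numpy default)
    return float(np.percentile(v, 75) - np.percentile(v, 25))


def summarize(features: pd.DataFrame, level: str = "eye") -> pd.DataFrame:
    """Median and IQR of sumdiff/MaxE/rmse/K at cube, region or eye level.

    Also reports ``median_sum_bins`` (the median over scans of the summed
    30-bin moduli, the per-region irregularity magnitude) and the scan
    count.  Quartiles use linear interpolation between order statistics.
    """
    if level not in _LEVEL_KEYS:
        raise ReferenceError(f"level must be one of {sorted(_LEVEL_KEYS)}")
    keys = _LEVEL_KEYS[level]
    _require_columns(features, keys + list(SUMMARY_STATS) + ["sum_bins"])
    rows = []
    for key_vals, grp in features.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        row = dict(zip(keys, key_vals))
        if "axial_length_mm" in grp.columns:
            row["axial_length_mm"] = float(grp["axial_length_mm"].iloc[0])
        for stat in SUMMARY_STATS:
            v = grp[stat].to_numpy(dtype=float)
            row[f"median_{stat}"] = float(np.median(v))
            row[f"iqr_{stat}"] = _iqr(v)
        row["median_sum_bins"] = float(np.median(grp["sum_bins"]))
        row["n_scans"] = len(grp)
        rows.append(row)
    return pd.DataFrame(rows)


def read_descriptor_mat(path, *, moduli_key: str = "moduli",
                        al_key: str = "axial_length_mm",
                        eye_key: str = "eye_id",
                        region_key: str = "region") -> pd.DataFrame:
    """Import precomputed per-scan spectra from a MATLAB .mat array.

    Expects a .mat file holding an (n_scans, 30) modulus array plus
    per-scan axial length, eye id and region vectors under the given keys;
    returns a descriptor-style DataFrame consumable by
    ``LeaveGroupOutScorer``.  Missing region/eye vectors fall back to a
    single pooled region and per-row eye ids.
    """
    data = sio.loadmat(path, squeeze_me=True)
    mods = np.atleast_2d(np.asarray(data[moduli_key], dtype=float))
    if mods.shape[1] != N_BINS:
        raise ReferenceError(
            f"expected {N_BINS} modulus columns in {moduli_key!r}, got {mods.shape[1]}"
        )
    n = mods.shape[0]
    al = np.asarray(data[al_key], dtype=float).reshape(-1)
    if al.size != n:
        raise ReferenceError("axial length vector length mismatch")
    eye = (np.asarray(data[eye_key]).reshape(-1).astype(str)
           if eye_key in data else np.array([f"eye{i}" for i in range(n)]))
    region = (np.asarray(data[region_key]).reshape(-1).astype(str)
              if region_key in data else np.full(n, "macula"))
    df = pd.DataFrame(mods, columns=list(MODULUS_COLUMNS))
    df.insert(0, "eye_id", eye)
    df.insert(1, "region", region)
    df.insert(2, "cube_id", "mat")
    df.insert(3, "scan_index", np.arange(n))
    df.insert(4, "axial_length_mm", al)
    df["K"] = np.nan
    df["K_raw"] = np.nan
    df["sum_bins"] = mods.sum(axis=1)
    df["retinal_length_mm"] = np.nan
    return df
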