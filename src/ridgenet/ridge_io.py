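"""Data model and I/O for extracted NMR ridge time series.

A *ridge* is one time-series NMR feature: a peak tracked through time,
carrying a chemical-shift trace (ppm) and an intensity trace.  Ridges are
grouped into experiments (one NMR run, one time grid) and experiments into
collections spanning conditions.  This module provides the canonical
tab-separated table format, nearest-neighbour gap filling, cross-experiment
feature matching by chemical shift, dual-channel (1H / 13C-HSQC)
normalization, and the labeled/unlabeled comparison scaling used before
pooled functional PCA.

Missing values are represented as NaN throughout; a missing intensity is
*not* zero — empty cells arise when a ridge could not be tracked at a time
point, typically because of a local baseline shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "AnnotationRecord",
    "Ridge",
    "Experiment",
    "RidgeCollection",
    "FeatureMatchTable",
    "MatchGroup",
    "read_ridge_table",
    "write_ridge_table",
    "fill_gaps",
    "match_features",
    "normalize_hsqc",
    "scale_for_comparison",
    "write_match_table",
]

RIDGE_TABLE_COLUMNS = (
    "experiment_id",
    "feature_id",
    "time",
    "ppm",
    "intensity",
    "channel",
    "labeled",
    "compound",
    "level",
)

CHANNELS = ("proton_1d", "hsqc_13c")


class RidgeTableError(ValueError):
    """Malformed ridge table input."""


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times, in hours."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 4:
            raise ValueError("time grid needs at least 4 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class AnnotationRecord:
    """Compound annotation with a 1–5 confidence level (5 = spike-in validated)."""

    compound: str
    confidence_level: int = 3

    def __post_init__(self) -> None:
        if self.confidence_level not in (1, 2, 3, 4, 5):
            raise ValueError("confidence_level must be in 1..5")


@dataclass
class Ridge:
    """One tracked NMR feature within a single experiment."""

    feature_id: str
    experiment_id: str
    ppm_trace: np.ndarray
    intensity_trace: np.ndarray
    channel: str = "proton_1d"
    labeled: bool = False
    annotation: AnnotationRecord | None = None
    fill_mask: np.ndarray | None = None  # True where a cell was gap-filled

    def __post_init__(self) -> None:
        self.ppm_trace = np.asarray(self.ppm_trace, dtype=float)
        self.intensity_trace = np.asarray(self.intensity_trace, dtype=float)
        if self.ppm_trace.shape != self.intensity_trace.shape:
            raise ValueError(
                f"ridge {self.feature_id!r}: ppm and intensity traces differ in length"
            )
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def mean_ppm(self) -> float:
        """Mean chemical shift over present (non-missing) trace values."""
        vals = self.ppm_trace[~np.isnan(self.ppm_trace)]
        if vals.size == 0:
            return math.nan
        return float(vals.mean())

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.intensity_trace).sum())

    @property
    def compound(self) -> str | None:
        return self.annotation.compound if self.annotation else None


@dataclass
class Experiment:
    """One NMR run: a shared time grid and its set of ridges."""

    experiment_id: str
    grid: TimeGrid
    ridges: dict[str, Ridge] = field(default_factory=dict)
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.grid)
        for r in self.ridges.values():
            if r.intensity_trace.size != n:
                raise ValueError(
                    f"ridge {r.feature_id!r} length {r.intensity_trace.size} "
                    f"!= grid length {n} in experiment {self.experiment_id!r}"
                )

    def add(self, ridge: Ridge) -> None:
        if ridge.intensity_trace.size != len(self.grid):
            raise ValueError("ridge length does not match experiment grid")
        self.ridges[ridge.feature_id] = ridge

    def __len__(self) -> int:
        return len(self.ridges)


@dataclass
class RidgeCollection:
    """A set of experiments with unique ids."""

    experiments: dict[str, Experiment] = field(default_factory=dict)

    def add(self, exp: Experiment) -> None:
        if exp.experiment_id in self.experiments:
            raise ValueError(f"duplicate experiment_id {exp.experiment_id!r}")
        self.experiments[exp.experiment_id] = exp

    def __len__(self) -> int:
        return len(self.experiments)

    def iter_ridges(self) -> Iterable[tuple[Experiment, Ridge]]:
        for exp in self.experiments.values():
            for ridge in exp.ridges.values():
                yield exp, ridge


@dataclass(frozen=True)
class MatchGroup:
    group_id: int
    members: tuple[tuple[str, str], ...]  # (experiment_id, feature_id)
    representative_ppm: float
    compound: str | None = None


@dataclass
class FeatureMatchTable:
    groups: list[MatchGroup]

    def member_to_group(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for g in self.groups:
            for m in g.members:
                if m in out:
                    raise ValueError(f"feature {m} appears in more than one group")
                out[m] = g.group_id
        return out


# ---------------------------------------------------------------------------
# Table I/O


def _parse_bool(x: object) -> bool:
    return str(x).strip().lower() in ("1", "true", "yes")


def read_ridge_table(path, sep: str = "\t") -> RidgeCollection:
    """Read the canonical long-format ridge table.

    One row per (experiment, feature, time point).  Empty ``ppm`` /
    ``intensity`` cells are recorded as missing (NaN), never as zero.  The
    grid of each experiment is the sorted union of its time values; features
    absent at some grid times get missing cells there.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("experiment_id", "feature_id", "time", "ppm", "intensity") if c not in df.columns]
    if missing:
        raise RidgeTableError(f"{path}: missing required columns {missing}")
    try:
        times = df["time"].astype(float)
    except ValueError as exc:
        bad = df.index[pd.to_numeric(df["time"], errors="coerce").isna()][0]
        raise RidgeTableError(f"{path}: malformed time value at data line {bad + 2}") from exc
    df = df.assign(time=times)

    coll = RidgeCollection()
    for exp_id, exp_df in df.groupby("experiment_id", sort=True):
        grid_times = np.unique(exp_df["time"].to_numpy())
        grid = TimeGrid(grid_times)
        t_index = {t: i for i, t in enumerate(grid.times)}
        exp = Experiment(experiment_id=str(exp_id), grid=grid)
        for feat_id, feat_df in exp_df.groupby("feature_id", sort=True):
            if feat_df["time"].duplicated().any():
                raise RidgeTableError(
                    f"{path}: duplicated time points for feature {feat_id!r} "
                    f"in experiment {exp_id!r}"
                )
            ppm = np.full(len(grid), np.nan)
            inten = np.full(len(grid), np.nan)
            for _, row in feat_df.iterrows():
                i = t_index[float(row["time"])]
                if str(row["ppm"]).strip() != "":
                    ppm[i] = float(row["ppm"])
                if str(row["intensity"]).strip() != "":
                    inten[i] = float(row["intensity"])
            first = feat_df.iloc[0]
            annotation = None
            compound = str(first.get("compound", "")).strip()
            if compound:
                level = str(first.get("level", "")).strip()
                annotation = AnnotationRecord(compound, int(level) if level else 3)
            exp.add(
                Ridge(
                    feature_id=str(feat_id),
                    experiment_id=str(exp_id),
                    ppm_trace=ppm,
                    intensity_trace=inten,
                    channel=str(first.get("channel", "")).strip() or "proton_1d",
                    labeled=_parse_bool(first.get("labeled", "")),
                    annotation=annotation,
                )
            )
        coll.add(exp)
    return coll


def write_ridge_table(coll: RidgeCollection, path, sep: str = "\t") -> None:
    """Write a collection in the canonical dialect (empty string = missing)."""
    rows = []
    for exp in coll.experiments.values():
        for ridge in exp.ridges.values():
            for i, t in enumerate(exp.grid.times):
                ppm = ridge.ppm_trace[i]
                inten = ridge.intensity_trace[i]
                rows.append(
                    {
                        "experiment_id": exp.experiment_id,
                        "feature_id": ridge.feature_id,
                        "time": repr(float(t)),
                        "ppm": "" if np.isnan(ppm) else repr(float(ppm)),
                        "intensity": "" if np.isnan(inten) else repr(float(inten)),
                        "channel": ridge.channel,
                        "labeled": "true" if ridge.labeled else "false",
                        "compound": ridge.annotation.compound if ridge.annotation else "",
                        "level": str(ridge.annotation.confidence_level) if ridge.annotation else "",
                    }
                )
    pd.DataFrame(rows, columns=list(RIDGE_TABLE_COLUMNS)).to_csv(path, sep=sep, index=False)


def write_match_table(table: FeatureMatchTable, coll: RidgeCollection, path, sep: str = "\t") -> None:
    rows = []
    for g in table.groups:
        for exp_id, feat_id in g.members:
            ridge = coll.experiments[exp_id].ridges[feat_id]
            rows.append(
                {
                    "group_id": g.group_id,
                    "experiment_id": exp_id,
                    "feature_id": feat_id,
                    "mean_ppm": ridge.mean_ppm,
                }
            )
    pd.DataFrame(rows, columns=["group_id", "experiment_id", "feature_id", "mean_ppm"]).to_csv(
        path, sep=sep, index=False
    )


DEFAULT_MAT_FIELDS = {
    "time": ("time", "times", "t"),
    "ppm": ("ppm", "ppms", "chemical_shift"),
    "intensity": ("intensity", "intensities", "ridge", "values"),
}


def read_mat_ridges(path, experiment_id: str | None = None, field_map=None) -> RidgeCollection:
    """Best-effort importer for MATLAB-container ridge-tracking files.

    Walks the container for struct arrays carrying per-ridge time / ppm /
    intensity vectors (field names configurable via ``field_map``) and
    maps them onto the canonical data model: one experiment whose grid is
    the union of ridge time points.  Containers vary; anything that cannot
    be interpreted raises with the offending field name.
    """
    from scipy.io import loadmat

    fields = {**DEFAULT_MAT_FIELDS, **(field_map or {})}
    mat = loadmat(path, squeeze_me=True, struct_as_record=False)

    def _get(obj, names):
        for n in names:
            if hasattr(obj, n):
                return np.atleast_1d(np.asarray(getattr(obj, n), dtype=float).ravel())
        return None

    ridges_raw = []
    stack = [v for k, v in mat.items() if not k.startswith("__")]
    while stack:
        obj = stack.pop()
        if isinstance(obj, np.ndarray) and obj.dtype == object:
            stack.extend(obj.ravel().tolist())
            continue
        t = _get(obj, fields["time"])
        inten = _get(obj, fields["intensity"])
        if t is None or inten is None:
            if hasattr(obj, "_fieldnames"):
                stack.extend(getattr(obj, n) for n in obj._fieldnames)
            continue
        ppm = _get(obj, fields["ppm"])
        ridges_raw.append((t, ppm, inten))
    if not ridges_raw:
        raise RidgeTableError(f"{path}: no ridge structures with fields {fields} found")

    exp_id = experiment_id or "mat_import"
    grid_times = np.unique(np.concatenate([t for t, _, _ in ridges_raw]))
    grid = TimeGrid(grid_times)
    index = {t: i for i, t in enumerate(grid.times)}
    exp = Experiment(exp_id, grid)
    for i, (t, ppm, inten) in enumerate(ridges_raw):
        pv = np.full(len(grid), np.nan)
        iv = np.full(len(grid), np.nan)
        for j, tj in enumerate(t):
            k = index[float(tj)]
            iv[k] = inten[j] if j < inten.size else np.nan
            if ppm is not None and j < ppm.size:
                pv[k] = ppm[j]
        exp.add(Ridge(f"ridge{i:04d}", exp_id, pv, iv))
    coll = RidgeCollection()
    coll.add(exp)
    return coll


# ---------------------------------------------------------------------------
# Gap filling


def fill_gaps(ridge: Ridge) -> Ridge:
    """Fill missing cells from the nearest observed time point.

    Ties (a gap equidistant from two observed points) resolve to the earlier
    time point.  Filling from neighbours rather than zero-filling avoids
    artifacts from local baseline shifts.  The returned ridge carries a
    ``fill_mask`` marking filled cells; present values are never altered.
    Idempotent.
    """
    inten = ridge.intensity_trace
    ppm = ridge.ppm_trace

    def _fill(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        present = ~np.isnan(trace)
        if not present.any():
            raise ValueError(f"ridge {ridge.feature_id!r}: all values missing")
        idx_present = np.flatnonzero(present)
        out = trace.copy()
        mask = np.zeros_like(trace, dtype=bool)
        for i in np.flatnonzero(~present):
            # argmin takes the first (earlier) index on a distance tie
            j = idx_present[np.argmin(np.abs(idx_present - i))]
            out[i] = trace[j]
            mask[i] = True
        return out, mask

    new_inten, mask_i = _fill(inten)
    new_ppm, _ = _fill(ppm) if not np.all(np.isnan(ppm)) else (ppm.copy(), None)
    return replace(ridge, intensity_trace=new_inten, ppm_trace=new_ppm, fill_mask=mask_i)


def fill_collection(coll: RidgeCollection) -> RidgeCollection:
    """Gap-fill every ridge; all-missing ridges are dropped with a report."""
    out = RidgeCollection()
    for exp in coll.experiments.values():
        new_exp = Experiment(exp.experiment_id, exp.grid, {}, dict(exp.condition))
        for ridge in exp.ridges.values():
            if np.all(np.isnan(ridge.intensity_trace)):
                continue
            new_exp.add(fill_gaps(ridge))
        out.add(new_exp)
    return out


# ---------------------------------------------------------------------------
# Cross-experiment feature matching


def match_features(coll: RidgeCollection, max_ppm: float = 0.01) -> FeatureMatchTable:
    """Match features across experiments by chemical shift.

    Annotated features are paired directly: two annotated features from
    different experiments match when they carry the same compound name and
    their mean chemical shifts are closest among that compound's features
    (greedy, ascending |Δppm|), so distinct multiplet components of one
    compound stay distinct.  Unannotated features are paired greedily by
    ascending |mean_ppm| distance with a hard ``max_ppm`` cap (default
    0.01 ppm); each feature is used at most once per experiment pair.
    Accepted pairs are closed transitively into groups.
    """
    feats: list[tuple[str, str, float, str | None]] = []
    for exp, ridge in coll.iter_ridges():
        mp = ridge.mean_ppm
        if math.isnan(mp):
            continue
        feats.append((exp.experiment_id, ridge.feature_id, mp, ridge.compound))

    # candidate pairs: (distance, ppm_lo, key_i, key_j)
    candidates = []
    for a in range(len(feats)):
        for b in range(a + 1, len(feats)):
            ea, fa, pa, ca = feats[a]
            eb, fb, pb, cb = feats[b]
            if ea == eb:
                continue
            d = abs(pa - pb)
            if ca is not None and cb is not None:
                if ca != cb:
                    continue  # different compounds never match
            elif ca is None and cb is None:
                if d > max_ppm:
                    continue
            else:
                continue  # annotated never pairs with unannotated
            candidates.append((d, min(pa, pb), (ea, fa), (eb, fb)))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    used: set[tuple[tuple[str, str], str]] = set()  # (feature key, partner experiment)
    for _, _, ki, kj in candidates:
        if (ki, kj[0]) in used or (kj, ki[0]) in used:
            continue
        used.add((ki, kj[0]))
        used.add((kj, ki[0]))
        union(ki, kj)

    clusters: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for e, f, _, _ in feats:
        key = (e, f)
        clusters.setdefault(find(key), []).append(key)

    groups = []
    gid = 0
    for root in sorted(clusters):
        members = tuple(sorted(clusters[root]))
        if len(members) < 2:
            continue
        ppms = [coll.experiments[e].ridges[f].mean_ppm for e, f in members]
        compounds = {coll.experiments[e].ridges[f].compound for e, f in members}
        compounds.discard(None)
        groups.append(
            MatchGroup(
                group_id=gid,
                members=members,
                representative_ppm=float(np.mean(ppms)),
                compound=compounds.pop() if len(compounds) == 1 else None,
            )
        )
        gid += 1
    return FeatureMatchTable(groups)


# ---------------------------------------------------------------------------
# Dual-channel normalization and comparison scaling


def normalize_hsqc(
    proton: Experiment,
    hsqc: Experiment,
    pyruvate_proton_ids: Sequence[str],
    pyruvate_hsqc_id: str,
    quantile: float = 0.10,
) -> tuple[float, Experiment]:
    """Scale a 13C-HSQC channel onto the 1H channel via the pyruvate peaks.

    Natural-abundance pyruvate gives a single methyl peak near 2.37 ppm in
    the 1H spectrum, split into four components for 13C-pyruvate; the
    decoupled HSQC keeps a single peak.  The per-time-point factor is
    f(t) = Σ(4 proton pyruvate intensities) / (HSQC pyruvate intensity),
    computed only at time points where the pyruvate peaks exceed their 10%
    intensity quantile, and averaged.  Every HSQC ridge is multiplied by the
    averaged factor.
    """
    if len(pyruvate_proton_ids) != 4:
        raise ValueError("expected the 4 proton pyruvate multiplet components")
    proton_sum = np.sum(
        [proton.ridges[fid].intensity_trace for fid in pyruvate_proton_ids], axis=0
    )
    hsqc_peak = hsqc.ridges[pyruvate_hsqc_id].intensity_trace
    if proton_sum.shape != hsqc_peak.shape:
        raise ValueError("channels must share a common resampled grid")

    keep = (proton_sum > np.nanquantile(proton_sum, quantile)) & (
        hsqc_peak > np.nanquantile(hsqc_peak, quantile)
    )
    keep &= ~np.isnan(proton_sum) & ~np.isnan(hsqc_peak)
    if not keep.any() or np.all(hsqc_peak[keep] <= 0):
        raise ValueError("no usable pyruvate time points for HSQC normalization")
    factor = float(np.mean(proton_sum[keep] / hsqc_peak[keep]))

    rescaled = Experiment(hsqc.experiment_id, hsqc.grid, {}, dict(hsqc.condition))
    for ridge in hsqc.ridges.values():
        rescaled.add(replace(ridge, intensity_trace=ridge.intensity_trace * factor))
    return factor, rescaled


@dataclass
class ScaledRidge:
    ridge: Ridge
    values: np.ndarray
    zero_variance: bool = False


def scale_for_comparison(
    groups: Mapping[str, Mapping[str, Sequence[Ridge]]],
    ddof: int = 1,
) -> dict[str, list[ScaledRidge]]:
    """Scale matched labeled/unlabeled ridge sets for pooled comparison.

    ``groups`` maps compound → {"labeled": [...], "unlabeled": [...]}.
    Step one divides every ridge of a compound by the maximum intensity of
    that compound's unlabeled form.  Step two standardizes (center, scale by
    sample sd) within each (experiment, labeling) stratum.  Zero-variance
    ridges are flagged rather than erroring, and should be excluded from
    variance-sensitive downstream stages.
    """
    out: dict[str, list[ScaledRidge]] = {}
    for compound, by_label in groups.items():
        unlabeled = list(by_label.get("unlabeled", ()))
        if not unlabeled:
            raise ValueError(f"compound {compound!r}: no unlabeled reference ridge")
        ref_max = max(float(np.nanmax(r.intensity_trace)) for r in unlabeled)
        if ref_max <= 0:
            raise ValueError(f"compound {compound!r}: unlabeled maximum is not positive")

        # stratify by (experiment, labeling)
        strata: dict[tuple[str, bool], list[Ridge]] = {}
        for label, ridges in by_label.items():
            for r in ridges:
                strata.setdefault((r.experiment_id, label == "labeled"), []).append(r)

        scaled: list[ScaledRidge] = []
        for ridges in strata.values():
            stacked = np.concatenate([r.intensity_trace / ref_max for r in ridges])
            mu = float(np.nanmean(stacked))
            sd = float(np.nanstd(stacked, ddof=ddof))
            for r in ridges:
                vals = r.intensity_trace / ref_max
                if sd > 0:
                    scaled.append(ScaledRidge(r, (vals - mu) / sd))
                else:
                    scaled.append(ScaledRidge(r, vals - mu, zero_variance=True))
        out[compound] = scaled
    return out
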