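"""Percent-of-control normalization, hit calling and cell aggregation.

The screening convention throughout is that each reading is expressed as
a percentage of its assay control, so lower values indicate stronger
bioactivity.  Within each bioassay category the overall mean and sample
standard deviation of the normalized responses define the activity
threshold ``mean - 1*SD``; a response at or below the threshold is a hit
(the comparison is inclusive).  The constituent assays of a category are
repeated measures of one sample's activity, combined into a single
category-level active/non-active call by a configurable rule.  Calls are
then aggregated into (taxon, bioregion, category) data cells as the
percentage of tested samples that were active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, NormalizationError
from .lineage import rekey_records

__all__ = [
    "CATEGORY_POOLED",
    "PER_ASSAY",
    "RULES",
    "ThresholdSpec",
    "normalize_to_control",
    "compute_threshold",
    "compute_thresholds",
    "call_activity",
    "summarize_cells",
    "ActivityScorer",
]

CATEGORY_POOLED = "pooled"
PER_ASSAY = "per_assay"
RULES = ("any", "all", "mean")

CELL_COLUMNS = ["taxon", "bioregion", "category", "n_tested", "n_active", "pct_active"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Activity threshold for one category (or one assay within it)."""

    category: str
    assay_id: str | None  # None when pooled over the category's assays
    mean: float
    sd: float
    threshold: float  # = mean - sd
    n_values: int
    pooling: str


def normalize_to_control(raw, control):
    """Express raw readings as a percentage of their control reading.

    Accepts scalars or aligned arrays; every control must be strictly
    positive.
    """
    raw_a = np.asarray(raw, dtype=float)
    ctl_a = np.asarray(control, dtype=float)
    if np.any(~np.isfinite(ctl_a)) or np.any(ctl_a <= 0):
        if ctl_a.ndim == 0:
            raise NormalizationError(
                f"control reading must be > 0, got {float(ctl_a)}"
            )
        bad = np.nonzero(~(np.isfinite(ctl_a) & (ctl_a > 0)))[0]
        raise NormalizationError(
            f"control reading must be > 0 (offending position(s): "
            f"{bad[:5].tolist()}{'...' if bad.size > 5 else ''})"
        )
    out = 100.0 * raw_a / ctl_a
    if np.isscalar(raw) or raw_a.ndim == 0:
        return float(out)
    return out


def _threshold_from_values(values: np.ndarray, category: str, assay_id: str | None,
                           pooling: str) -> ThresholdSpec:
    values = np.asarray(values, dtype=float)
    scope = f"category {category!r}" + (f", assay {assay_id!r}" if assay_id else "")
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 response values to set a threshold for {scope}; "
            f"got {values.size}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            f"zero response variance in {scope}; threshold equals the mean",
            stacklevel=3,
        )
    return ThresholdSpec(
        category=category,
        assay_id=assay_id,
        mean=mean,
        sd=sd,
        threshold=mean - sd,
        n_values=int(values.size),
        pooling=pooling,
    )


def compute_threshold(
    records: pd.DataFrame, category: str, pooling: str = CATEGORY_POOLED
):
    """Mean - 1 SD activity threshold for one bioassay category.

    With category pooling (the default) all constituent assays' values
    are pooled before the mean and sample SD (n-1 denominator) are taken,
    returning a single :class:`ThresholdSpec`.  With per-assay pooling a
    dict of specs keyed by assay id is returned.
    """
    sub = records.loc[records["category"] == category]
    if pooling == CATEGORY_POOLED:
        return _threshold_from_values(
            sub["response"].to_numpy(), category, None, pooling
        )
    if pooling == PER_ASSAY:
        out = {}
        for assay_id, grp in sub.groupby("assay_id", sort=True):
            out[assay_id] = _threshold_from_values(
                grp["response"].to_numpy(), category, str(assay_id), pooling
            )
        if not out:
            raise InsufficientDataError(f"no records for category {category!r}")
        return out
    raise ValueError(f"unknown pooling {pooling!r}")


def compute_thresholds(
    records: pd.DataFrame, pooling: str = CATEGORY_POOLED
) -> pd.DataFrame:
    """Threshold table over every category present in ``records``."""
    rows = []
    for category in sorted(records["category"].unique()):
        spec = compute_threshold(records, category, pooling)
        specs = [spec] if isinstance(spec, ThresholdSpec) else list(spec.values())
        rows.extend(
            (s.category, s.assay_id, s.mean, s.sd, s.threshold, s.n_values, s.pooling)
            for s in specs
        )
    return pd.DataFrame(
        rows,
        columns=["category", "assay_id", "mean", "sd", "threshold",
                 "n_values", "pooling"],
    )


def _threshold_lookup(thresholds) -> tuple[dict, dict]:
    """Normalize threshold input to (per-category, per-(category, assay)) maps."""
    if isinstance(thresholds, ThresholdSpec):
        thresholds = [thresholds]
    if isinstance(thresholds, dict):
        thresholds = list(thresholds.values())
    if isinstance(thresholds, pd.DataFrame):
        specs = [
            ThresholdSpec(
                category=r.category,
                assay_id=None if pd.isna(r.assay_id) or r.assay_id in ("", None)
                else str(r.assay_id),
                mean=float(r.mean), sd=float(r.sd), threshold=float(r.threshold),
                n_values=int(r.n_values), pooling=str(r.pooling),
            )
            for r in thresholds.itertuples(index=False)
        ]
    else:
        specs = list(thresholds)
    by_category = {s.category: s for s in specs if s.assay_id is None}
    by_assay = {(s.category, s.assay_id): s for s in specs if s.assay_id is not None}
    return by_category, by_assay


def call_activity(
    records: pd.DataFrame,
    thresholds,
    rule: str = "any",
    return_flags: bool = False,
):
    """Assign each sample active/non-active per bioassay category.

    Per-assay flags are ``response <= threshold`` (inclusive at
    equality).  Category-level calls combine a sample's repeated
    measures by ``rule``: ``any`` (default; active if any constituent
    assay is at/below threshold), ``all``, or ``mean`` (mean response
    at/below the category threshold).  Samples measured in only a subset
    of a category's assays are still called on the available assays; the
    number of such partially-measured samples is reported in
    ``calls.attrs["n_partial_samples"]``.

    Returns the calls table, plus the record-level flag table when
    ``return_flags`` is set.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    by_category, by_assay = _threshold_lookup(thresholds)

    flags = records.copy()
    thr = np.empty(len(flags), dtype=float)
    cats = flags["category"].to_numpy()
    assays = flags["assay_id"].to_numpy()
    for i, (c, a) in enumerate(zip(cats, assays)):
        spec = by_assay.get((c, a)) or by_category.get(c)
        if spec is None:
            raise KeyError(
                f"no threshold available for category {c!r}, assay {a!r}"
            )
        thr[i] = spec.threshold
    flags["threshold"] = thr
    flags["assay_active"] = flags["response"].to_numpy() <= thr

    id_cols = ["sample_id", "category"]
    meta_cols = [c for c in ("phylum", "genus", "bioregion") if c in flags.columns]
    grouped = flags.groupby(id_cols, sort=True)
    agg = grouped.agg(
        n_assays=("assay_id", "nunique"),
        n_assays_active=("assay_active", "sum"),
        mean_response=("response", "mean"),
        mean_threshold=("threshold", "mean"),
        **{c: (c, "first") for c in meta_cols},
    ).reset_index()

    if rule == "any":
        active = agg["n_assays_active"] > 0
    elif rule == "all":
        active = agg["n_assays_active"] == agg["n_assays"]
    else:  # mean: compare the mean response with the (mean) threshold
        active = agg["mean_response"] <= agg["mean_threshold"]
    agg["active"] = active.to_numpy()
    agg["rule"] = rule

    n_full = {c: records.loc[records["category"] == c, "assay_id"].nunique()
              for c in np.unique(cats)}
    partial = agg["n_assays"] < agg["category"].map(n_full)
    calls = agg[id_cols + meta_cols +
                ["active", "rule", "n_assays", "n_assays_active"]].copy()
    calls.attrs["n_partial_samples"] = int(partial.sum())
    if return_flags:
        return calls, flags
    return calls


def summarize_cells(calls: pd.DataFrame, level: str = "phylum") -> pd.DataFrame:
    """Aggregate calls into (taxon, bioregion, category) cell summaries.

    ``n_tested`` counts distinct sample ids; ``pct_active`` is
    ``100 * n_active / n_tested``.  Cells with no tested samples are
    simply absent.
    """
    keyed, _ = rekey_records(calls, level)
    rows = []
    for (taxon, bioregion, category), grp in keyed.groupby(
        ["taxon", "bioregion", "category"], sort=True
    ):
        dedup = grp.drop_duplicates("sample_id")
        n_tested = len(dedup)
        n_active = int(dedup["active"].sum())
        rows.append(
            (taxon, bioregion, category, n_tested, n_active,
             100.0 * n_active / n_tested)
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


class ActivityScorer(BaseEstimator):
    """Threshold-based hit caller with the scikit-learn estimator API.

    ``fit`` learns the per-category activity thresholds (mean - 1 SD of
    the normalized responses); ``transform`` turns a record table into
    category-level activity calls using those thresholds.  Fitting and
    calling may use different tables, e.g. thresholds from a full
    library applied to a subset.

    Parameters
    ----------
    pooling:
        ``"pooled"`` (category-pooled mean/SD, default) or
        ``"per_assay"``.
    rule:
        Repeated-measure combination rule: ``"any"`` (default),
        ``"all"`` or ``"mean"``.
    """

    def __init__(self, pooling: str = CATEGORY_POOLED, rule: str = "any"):
        self.pooling = pooling
        self.rule = rule

    def fit(self, records: pd.DataFrame, y=None):
        if rule := (self.rule not in RULES and self.rule):
            raise ValueError(f"unknown rule {rule!r}")
        self.thresholds_ = compute_thresholds(records, self.pooling)
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("ActivityScorer must be fitted before transform")
        return call_activity(records, self.thresholds_, self.rule)

    def fit_transform(self, records: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(records).transform(records)

    def cell_summaries(
        self, records: pd.DataFrame, level: str = "phylum"
    ) -> pd.DataFrame:
        return summarize_cells(self.transform(records), level)
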