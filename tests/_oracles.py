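"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: thresholds are
computed by two-pass mean/SD loops, calls by per-record dictionaries,
and cell tallies by explicit iteration, so that agreement with the
vectorized implementations is informative.
"""

from __future__ import annotations

import math
from collections import defaultdict


def brute_threshold(values: list[float]) -> tuple[float, float, float]:
    """Two-pass mean / sample SD / (mean - sd) threshold."""
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    sd = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
    return mean, sd, mean - sd


def brute_category_thresholds(records: list[dict], pooling: str) -> dict:
    """Thresholds keyed by category (pooled) or (category, assay)."""
    scopes: dict = defaultdict(list)
    for r in records:
        if pooling == "pooled":
            scopes[r["category"]].append(r["response"])
        else:
            scopes[(r["category"], r["assay_id"])].append(r["response"])
    return {k: brute_threshold(v) for k, v in scopes.items()}


def brute_calls(records: list[dict], thresholds: dict, rule: str,
                pooling: str) -> dict:
    """Per (sample_id, category) active flag plus per-assay flags."""
    by_sample: dict = defaultdict(list)
    for r in records:
        by_sample[(r["sample_id"], r["category"])].append(r)
    out = {}
    for key, rows in by_sample.items():
        _, category = key
        flags = []
        thr_vals = []
        for r in rows:
            thr = (
                thresholds[category][2]
                if pooling == "pooled"
                else thresholds[(category, r["assay_id"])][2]
            )
            flags.append(r["response"] <= thr)
            thr_vals.append(thr)
        if rule == "any":
            active = any(flags)
        elif rule == "all":
            active = all(flags)
        else:  # mean response vs mean threshold
            mean_resp = sum(r["response"] for r in rows) / len(rows)
            active = mean_resp <= sum(thr_vals) / len(thr_vals)
        out[key] = {
            "active": active,
            "per_assay": {r["assay_id"]: f for r, f in zip(rows, flags)},
            "phylum": rows[0]["phylum"],
            "genus": rows[0].get("genus"),
            "bioregion": rows[0]["bioregion"],
        }
    return out


def brute_cells(calls: dict, level: str) -> dict:
    """(taxon, bioregion, category) -> (n_tested, n_active, pct_active)."""
    tally: dict = defaultdict(lambda: [0, 0])
    for (sample_id, category), call in calls.items():
        taxon = call["phylum"] if level == "phylum" else call["genus"]
        if taxon is None:
            continue
        cell = (taxon, call["bioregion"], category)
        tally[cell][0] += 1
        tally[cell][1] += int(call["active"])
    return {
        cell: (n, k, 100.0 * k / n) for cell, (n, k) in tally.items()
    }
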