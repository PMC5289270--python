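"""End-to-end drivers over the synthetic benchmark.

These functions tie the stages together: screen every candidate pair
against the template library (with a shared alignment cache), tabulate
per-template TMmin values and interface validity, and derive detection
rates, planted-template recovery, and the thinned-library completeness
study from the single screen table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .precedent import AlignmentCache, build_interaction_model, tmmin_for_template, validate_interface
from .stats import RateCurve, completeness_corrected_rate, precedent_rate_curve
from .synthetic_data import Benchmark

__all__ = [
    "screen_benchmark",
    "best_hits",
    "rate_curves_by_label",
    "planted_recovery_rate",
    "thinned_library_study",
]


def screen_benchmark(bench: Benchmark, validate_threshold: float = 0.35) -> pd.DataFrame:
    """Score every (pair, template) combination of a benchmark.

    Returns one row per combination with the winning chain assignment's
    TM-scores and TMmin; combinations reaching ``validate_threshold`` are
    built into interaction models and validated (below it, validity is
    left undetermined to save superpositions that no threshold will use).
    """
    cache = AlignmentCache()
    rows = []
    models = []
    for pair in bench.pairs:
        for ma in pair.models_a:
            for mb in pair.models_b:
                for dimer in bench.library:
                    hit = tmmin_for_template(ma, mb, dimer, pair_id=pair.pair_id, cache=cache)
                    valid, size, clashes = None, None, None
                    if hit.tmmin >= validate_threshold:
                        model = build_interaction_model(ma, mb, dimer, hit)
                        valid, size, clashes = validate_interface(model)
                        models.append(model)
                    rows.append(
                        {
                            "pair_id": pair.pair_id,
                            "label": pair.label,
                            "kind": pair.kind,
                            "planted_template": pair.template or "",
                            "template": dimer.id,
                            "assignment": hit.assignment,
                            "tm_a": hit.tm_a,
                            "tm_b": hit.tm_b,
                            "tmmin": hit.tmmin,
                            "valid": valid,
                            "interface_size": size,
                            "clash_count": clashes,
                        }
                    )
    df = pd.DataFrame(rows)
    df.attrs["models"] = models
    return df


def best_hits(
    screen: pd.DataFrame, threshold: float, templates: set[str] | None = None
) -> pd.DataFrame:
    """Best valid precedent per pair at a TMmin threshold.

    Rows are ranked by decreasing TMmin (ties by template id, then
    assignment); only valid-interface combinations can win.  Restricting
    ``templates`` emulates a thinned library.
    """
    df = screen[screen["tmmin"] >= threshold]
    df = df[df["valid"] == True]  # noqa: E712 - None means "not evaluated"
    if templates is not None:
        df = df[df["template"].isin(templates)]
    if df.empty:
        return df.copy()
    df = df.sort_values(
        ["pair_id", "tmmin", "template", "assignment"],
        ascending=[True, False, True, True],
    )
    return df.groupby("pair_id", as_index=False).first()


def _per_pair_best_tmmin(
    screen: pd.DataFrame, templates: set[str] | None = None
) -> pd.Series:
    """Best valid TMmin per pair (NaN when no valid combination)."""
    df = screen[screen["valid"] == True]  # noqa: E712
    if templates is not None:
        df = df[df["template"].isin(templates)]
    best = df.groupby("pair_id")["tmmin"].max()
    all_pairs = screen["pair_id"].unique()
    return best.reindex(all_pairs)


def rate_curves_by_label(
    screen: pd.DataFrame,
    thresholds=(0.4, 0.5, 0.6),
    templates: set[str] | None = None,
) -> dict[str, RateCurve]:
    """Precedent rate curves for interacting and non-interacting pairs."""
    labels = screen[["pair_id", "label"]].drop_duplicates().set_index("pair_id")["label"]
    best = _per_pair_best_tmmin(screen, templates)
    out: dict[str, RateCurve] = {}
    for label in labels.unique():
        pair_ids = labels[labels == label].index
        vals = [None if np.isnan(v) else float(v) for v in best.loc[pair_ids]]
        out[label] = precedent_rate_curve(vals, thresholds)
    return out


def planted_recovery_rate(screen: pd.DataFrame, threshold: float = 0.6) -> float:
    """Fraction of planted positive pairs whose own template is recovered."""
    pos = screen[screen["kind"] == "positive"]
    planted = pos[["pair_id", "planted_template"]].drop_duplicates().set_index("pair_id")
    best = best_hits(screen, threshold)
    if best.empty:
        return 0.0
    best = best.set_index("pair_id")
    hits = 0
    for pid, row in planted.iterrows():
        if pid in best.index and best.loc[pid, "template"] == row["planted_template"]:
            hits += 1
    return hits / len(planted)


def thinned_library_study(
    screen: pd.DataFrame,
    threshold: float = 0.6,
    fractions=(0.25, 0.5),
) -> pd.DataFrame:
    """Completeness-correction check by artificially thinning the library.

    For each retained fraction f, the library is cut to its first
    ceil(f * T) templates, positive and negative precedent rates are
    re-measured, and the corrected negative rate
    100 * negative_rate / positive_rate is compared with the full-library
    negative rate (in %).
    """
    all_templates = sorted(screen["template"].unique())
    full = rate_curves_by_label(screen, thresholds=[threshold])
    full_neg = 100.0 * full["non-interacting"].rate_at(threshold)
    rows = []
    for f in fractions:
        keep = set(all_templates[: max(1, int(np.ceil(f * len(all_templates))))])
        curves = rate_curves_by_label(screen, thresholds=[threshold], templates=keep)
        pos = 100.0 * curves["interacting"].rate_at(threshold)
        neg = 100.0 * curves["non-interacting"].rate_at(threshold)
        corrected = completeness_corrected_rate(neg, pos) if pos > 0 else float("nan")
        rows.append(
            {
                "fraction": f,
                "n_templates": len(keep),
                "positive_rate_pct": pos,
                "negative_rate_pct": neg,
                "corrected_negative_rate_pct": corrected,
                "full_library_negative_rate_pct": full_neg,
            }
        )
    return pd.DataFrame(rows)
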