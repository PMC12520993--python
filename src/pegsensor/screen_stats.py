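"""Enrichment statistics for sensor-calibrated pegRNA screens.

Counts are normalized with median-of-ratios size factors; each design's log2
fold change is computed from replicate medians with a pseudocount of 1;
Z-scores standardize LFCs over the considered subset (population standard
deviation); significance comes from a two-sided empirical null built from
the silent (synonymous) control designs with Benjamini-Hochberg correction.
Sensor calibration restricts the considered subset to designs whose own
sensor demonstrates at least a minimum correct-editing percentage with a
minimum number of sensor reads, and the statistics are recomputed over that
subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_THRESHOLD_SWEEP = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample factors, scaled to geometric mean 1.

    Computed over designs with positive counts in all samples; if none
    exist, falls back to total-count scaling with a warning.
    """
    counts = counts.astype(float)
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        import warnings

        warnings.warn(
            "no design has positive counts in all samples; "
            "falling back to total-count scaling",
            stacklevel=2,
        )
        factors = counts.sum(axis=0)
    else:
        log_ref = np.log(positive).mean(axis=1)
        factors = np.exp(np.log(positive).sub(log_ref, axis=0).median(axis=0))
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.astype(float).div(size_factors(counts), axis=1)


def compute_lfc(
    counts: pd.DataFrame,
    control_samples: list,
    treated_samples: list,
    min_control_mean: float = 10.0,
) -> pd.DataFrame:
    """Per-design log2 fold change of treated vs control replicate medians.

    ``lfc = log2(median(norm treated) + 1) - log2(median(norm control) + 1)``.
    Designs whose normalized control mean falls below ``min_control_mean``
    are flagged and carry no LFC (excluded from downstream statistics but
    retained in the output).
    """
    if not control_samples or not treated_samples:
        raise ValueError("control and treated sample sets must be non-empty")
    norm = normalize_counts(counts[list(control_samples) + list(treated_samples)])
    control = norm[list(control_samples)]
    treated = norm[list(treated_samples)]
    result = pd.DataFrame(index=counts.index)
    result["control_mean"] = control.mean(axis=1)
    result["control_median"] = control.median(axis=1)
    result["treated_median"] = treated.median(axis=1)
    result["passed_count_filter"] = result["control_mean"] >= min_control_mean
    result["lfc"] = np.log2(result["treated_median"] + 1.0) - np.log2(
        result["control_median"] + 1.0
    )
    result.loc[~result["passed_count_filter"], "lfc"] = np.nan
    return result


def zscores(results: pd.DataFrame, considered: pd.Series | None = None) -> pd.DataFrame:
    """Standardize LFCs over the considered subset (population sd)."""
    out = results.copy()
    mask = _considered_mask(out, considered)
    lfc = out.loc[mask, "lfc"]
    if len(lfc) < 2:
        raise ValueError("need at least 2 considered designs for Z-scores")
    sd = lfc.std(ddof=0)
    out["zscore"] = np.nan
    out.loc[mask, "zscore"] = (lfc - lfc.mean()) / sd
    return out


def _considered_mask(results: pd.DataFrame, considered) -> pd.Series:
    mask = results["lfc"].notna()
    if considered is not None:
        mask &= considered.reindex(results.index, fill_value=False)
    return mask


def empirical_fdr(
    results: pd.DataFrame,
    silent_control_ids,
    considered: pd.Series | None = None,
    min_controls: int = 20,
) -> pd.DataFrame:
    """Two-sided empirical p-values from the silent-control null, BH-adjusted.

    ``p_i = (1 + #{silent s: |lfc_s| >= |lfc_i|}) / (1 + n_silent)`` over the
    considered subset; FDR is Benjamini-Hochberg across considered designs.
    """
    out = results.copy()
    mask = _considered_mask(out, considered)
    silent = out.index.intersection(pd.Index(silent_control_ids))
    null = out.loc[out.index.isin(silent) & mask, "lfc"].abs().to_numpy()
    if null.size < min_controls:
        raise ValueError(
            f"only {null.size} silent controls in the considered set; "
            f"need >= {min_controls}"
        )
    null_sorted = np.sort(null)
    obs = out.loc[mask, "lfc"].abs().to_numpy()
    n_ge = null_sorted.size - np.searchsorted(null_sorted, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + null_sorted.size)
    out["p_emp"] = np.nan
    out["fdr"] = np.nan
    out.loc[mask, "p_emp"] = p
    out.loc[mask, "fdr"] = multipletests(p, method="fdr_bh")[1]
    return out


def summarize_editing(
    summaries: pd.DataFrame, samples: list | None = None
) -> pd.DataFrame:
    """Pool per-sample editing summaries into one row per design.

    Outcome counts are summed over the chosen samples; the pooled correct
    percentage (background-subtracted when available) is read-weighted.
    """
    df = summaries
    if samples is not None:
        df = df[df["sample_id"].isin(samples)]
    pct_col = (
        "correct_pct_bg_subtracted"
        if "correct_pct_bg_subtracted" in df.columns
        else "correct_pct"
    )
    grouped = df.groupby("design_id")
    n_reads = grouped["n_sensor_reads"].sum()
    weighted = grouped.apply(
        lambda g: np.average(g[pct_col], weights=g["n_sensor_reads"])
        if g["n_sensor_reads"].sum() > 0
        else 0.0,
        include_groups=False,
    )
    return pd.DataFrame(
        {"n_sensor_reads": n_reads, "correct_pct": weighted}
    )


def sensor_calibrate(
    results: pd.DataFrame,
    editing: pd.DataFrame,
    silent_control_ids,
    min_correct_pct: float = 10.0,
    min_sensor_reads: int = 10,
) -> pd.DataFrame:
    """Restrict statistics to designs whose sensors pass the editing bar.

    ``editing`` is the per-design table from :func:`summarize_editing`.
    Z-scores and empirical FDR are recomputed over the calibrated subset.
    """
    out = results.copy()
    joined = editing.reindex(out.index)
    out["sensor_correct_pct"] = joined["correct_pct"]
    out["sensor_reads"] = joined["n_sensor_reads"].fillna(0).astype(int)
    out["passed_calibration"] = (
        (out["sensor_correct_pct"] >= min_correct_pct)
        & (out["sensor_reads"] >= min_sensor_reads)
        & out["lfc"].notna()
    )
    out["calibration_threshold_used"] = min_correct_pct
    out = zscores(out, out["passed_calibration"])
    out = empirical_fdr(out, silent_control_ids, out["passed_calibration"])
    return out


def threshold_sweep(
    results: pd.DataFrame,
    editing: pd.DataFrame,
    silent_control_ids,
    thresholds=DEFAULT_THRESHOLD_SWEEP,
    min_sensor_reads: int = 10,
    fdr_cutoff: float = 0.05,
    truth_effect: pd.Series | None = None,
) -> pd.DataFrame:
    """Significant-design counts (and optional truth correlation) per
    minimum correct-editing threshold."""
    rows = []
    for threshold in thresholds:
        calibrated = sensor_calibrate(
            results, editing, silent_control_ids, threshold, min_sensor_reads
        )
        mask = calibrated["passed_calibration"]
        row = {
            "min_correct_pct": threshold,
            "n_considered": int(mask.sum()),
            "n_significant": int(
                ((calibrated["fdr"] < fdr_cutoff) & mask).sum()
            ),
        }
        if truth_effect is not None:
            sub = calibrated.loc[mask, "lfc"]
            truth = truth_effect.reindex(sub.index)
            row["spearman_lfc_vs_effect"] = (
                stats.spearmanr(sub, truth).statistic if len(sub) >= 3 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def best_per_variant(
    results: pd.DataFrame,
    editing: pd.DataFrame,
    variant_of: pd.Series,
    rank_of: pd.Series | None = None,
) -> pd.DataFrame:
    """Variant-level results from each variant's most efficient calibrated
    design (ties: more sensor reads, then better design rank)."""
    df = results.copy()
    df["variant_id"] = variant_of.reindex(df.index)
    df["_rank"] = (
        rank_of.reindex(df.index) if rank_of is not None else range(len(df))
    )
    rows = []
    for variant_id, group in df.groupby("variant_id", sort=True):
        calibrated = group[group["passed_calibration"]]
        if calibrated.empty:
            rows.append(
                {
                    "variant_id": variant_id,
                    "best_design_id": None,
                    "n_designs_passing": 0,
                    "variant_lfc": np.nan,
                    "variant_zscore": np.nan,
                    "best_correct_pct": np.nan,
                }
            )
            continue
        ordered = calibrated.sort_values(
            by=["sensor_correct_pct", "sensor_reads", "_rank"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        best = ordered.iloc[0]
        rows.append(
            {
                "variant_id": variant_id,
                "best_design_id": ordered.index[0],
                "n_designs_passing": int(len(calibrated)),
                "variant_lfc": best["lfc"],
                "variant_zscore": best.get("zscore", np.nan),
                "best_correct_pct": best["sensor_correct_pct"],
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


def correlate(
    table: pd.DataFrame,
    target_column: str,
    feature_columns: list | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-feature correlation with a target column.

    Spearman by default (average ranks on ties); pairs with fewer than 3
    complete observations report NaN.
    """
    if feature_columns is None:
        feature_columns = [
            c
            for c in table.columns
            if c != target_column and pd.api.types.is_numeric_dtype(table[c])
        ]
    func = {
        "spearman": stats.spearmanr,
        "pearson": stats.pearsonr,
    }[method]
    rows = []
    for feature in feature_columns:
        sub = table[[feature, target_column]].dropna()
        rho = (
            func(sub[feature], sub[target_column]).statistic
            if len(sub) >= 3
            else np.nan
        )
        rows.append({"feature": feature, "coefficient": rho, "n": len(sub)})
    return pd.DataFrame(rows)


def delta_z(
    variant_results: pd.DataFrame, external_z: pd.DataFrame
) -> pd.DataFrame:
    """Difference between endogenous (prime editing) and external (cDNA)
    Z-scores per variant; variants missing on either side are flagged."""
    out = variant_results.copy()
    ext = external_z.set_index("variant_id")["zscore"] \
        if "variant_id" in external_z.columns else external_z["zscore"]
    out["external_zscore"] = ext.reindex(out.index)
    out["delta_z"] = out["variant_zscore"] - out["external_zscore"]
    out["delta_z_missing"] = (
        out["variant_zscore"].isna() | out["external_zscore"].isna()
    )
    return out
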