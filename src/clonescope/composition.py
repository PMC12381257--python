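"""Cell-type composition shifts between two conditions.

Per cell type the log2 fold change of proportions between conditions is
tested with a label-permutation p-value and a within-condition bootstrap
confidence interval; the joint significance rule is p < alpha AND
|log2FC| > fc_threshold (the magnitude rule; the sign is reported
separately).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _log2fc(count_a: np.ndarray, n_a: int, count_b: np.ndarray, n_b: int) -> np.ndarray:
    # pseudocount of 1 cell replaces empty types so the ratio stays finite;
    # computed as a difference of logs so swapping conditions negates exactly
    pa = np.maximum(count_a, 1) / n_a
    pb = np.maximum(count_b, 1) / n_b
    return np.log2(pa) - np.log2(pb)


def proportion_test(
    cell_type_labels,
    condition_labels,
    n_perm: int = 1000,
    n_boot: int = 1000,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    seed: int = 0,
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation test plus bootstrap CI for per-type proportion shifts.

    The observed statistic per type is log2(prop_A / prop_B), with a
    pseudocount of one cell substituted for empty types (flagged in the
    output). The null permutes condition labels over cells; the two-sided p
    is (1 + #{|log2FC*| >= |log2FC|}) / (1 + n_perm). The 95% percentile CI
    comes from resampling cells with replacement within each condition.
    A type is significant iff p < alpha and |log2FC| > fc_threshold.
    """
    types = pd.Series(np.asarray(cell_type_labels, dtype=object))
    cond = pd.Series(np.asarray(condition_labels, dtype=object))
    if len(types) != len(cond):
        raise ValueError("label vectors differ in length")
    levels = list(conditions) if conditions else list(pd.unique(cond.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    a_name, b_name = levels
    is_a = (cond == a_name).to_numpy()
    is_b = (cond == b_name).to_numpy()
    n_a, n_b = int(is_a.sum()), int(is_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("a condition has zero cells")
    type_names = pd.unique(types)
    if len(type_names) < 2:
        raise ValueError("need >= 2 cell types")
    codes = pd.Categorical(types, categories=type_names).codes
    T = len(type_names)

    count_a = np.bincount(codes[is_a], minlength=T)
    count_b = np.bincount(codes[is_b], minlength=T)
    obs = _log2fc(count_a, n_a, count_b, n_b)

    rng = np.random.default_rng(seed)
    used = is_a | is_b
    codes_u = codes[used]
    a_u = is_a[used]
    exceed = np.zeros(T)
    for _ in range(n_perm):
        perm = rng.permutation(a_u)
        ca = np.bincount(codes_u[perm], minlength=T)
        cb = np.bincount(codes_u[~perm], minlength=T)
        exceed += np.abs(_log2fc(ca, n_a, cb, n_b)) >= np.abs(obs)
    p = (1.0 + exceed) / (1.0 + n_perm)

    # bootstrap: resample cells with replacement within each condition
    pa_emp = count_a / n_a
    pb_emp = count_b / n_b
    boot_a = rng.multinomial(n_a, pa_emp, size=n_boot)
    boot_b = rng.multinomial(n_b, pb_emp, size=n_boot)
    boot = _log2fc(boot_a, n_a, boot_b, n_b)
    ci_low = np.percentile(boot, 2.5, axis=0)
    ci_high = np.percentile(boot, 97.5, axis=0)

    return pd.DataFrame(
        {
            "cell_type": type_names,
            f"count_{a_name}": count_a,
            f"count_{b_name}": count_b,
            f"prop_{a_name}": count_a / n_a,
            f"prop_{b_name}": count_b / n_b,
            "log2fc": obs,
            "pseudocount_used": (count_a == 0) | (count_b == 0),
            "p_value": p,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "significant": (p < alpha) & (np.abs(obs) > fc_threshold),
        }
    )
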