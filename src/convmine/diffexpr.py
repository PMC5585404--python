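"""Per-dataset differential expression between origin and target cells.

Each gene receives a linear fold change (target mean over origin mean), a
two-sample p-value, and a three-way direction call in {up, down, none}.

The fold change is computed on the linear intensity scale. P-values come from
Welch's unequal-variance t-test on log2 intensities and require at least two
replicates per group; datasets with a single sample in either group (common in
published conversion experiments) fall back to a fold-change-only call when
``single_sample_mode="fc_only"``.

No per-dataset multiple-testing correction is applied: the raw p < 0.05
threshold is deliberate, because robustness comes from requiring agreement
across independent datasets downstream (see :mod:`convmine.consensus`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from convmine.io import ExpressionDataset

log = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"

#: Relative pseudocount applied to group means before division, as a fraction
#: of the global matrix median. Guards against zero means on sparse data.
PSEUDOCOUNT_FRACTION = 1e-6


@dataclass(frozen=True)
class DEThresholds:
    """Significance and effect-size gates for direction calling.

    ``p_max`` — p-value threshold for testable genes (default 0.05).
    ``fc_min`` — linear fold-change magnitude a gene must reach when p-values
    are unavailable (default 1.5).
    ``single_sample_mode`` — ``"fc_only"`` calls untestable genes by fold
    change alone; ``"strict"`` never calls them.
    ``test`` — the two-sample statistic: ``"student"`` (equal-variance t,
    exact when the two groups share a noise variance, as same-platform
    replicate arrays do) or ``"welch"`` (unequal-variance; its estimated
    Satterthwaite df costs real power at 2–3 replicates per group).
    """

    p_max: float = 0.05
    fc_min: float = 1.5
    single_sample_mode: str = "fc_only"
    test: str = "student"

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if self.single_sample_mode not in ("fc_only", "strict"):
            raise ValueError("single_sample_mode must be 'fc_only' or 'strict'")
        if self.test not in ("student", "welch"):
            raise ValueError("test must be 'student' or 'welch'")


@dataclass
class DEResult:
    """Per-gene differential-expression table for one dataset.

    ``table`` columns: fc_linear, log2fc, p_value (NaN when untestable),
    testable (bool), direction.
    """

    dataset_id: str
    table: pd.DataFrame

    @property
    def directions(self) -> pd.Series:
        return self.table["direction"]

    @property
    def fc_linear(self) -> pd.Series:
        return self.table["fc_linear"]


def fold_change(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene linear fold change target/origin and its log2.

    Group means are floored at a small pseudocount (a 1e-6 fraction of the
    global matrix median, or 1e-6 if the median is zero) before division, so
    the ratio is always finite and positive.
    """
    origin = ds.values[ds.origin_samples]
    target = ds.values[ds.target_samples]
    if origin.shape[1] == 0 or target.shape[1] == 0:
        raise ValueError(f"{ds.dataset_id}: empty group")
    floor = PSEUDOCOUNT_FRACTION * float(np.median(ds.values.to_numpy()))
    if floor <= 0:
        floor = PSEUDOCOUNT_FRACTION
    mo = np.maximum(origin.mean(axis=1).to_numpy(), floor)
    mt = np.maximum(target.mean(axis=1).to_numpy(), floor)
    fc = mt / mo
    return pd.DataFrame({"fc_linear": fc, "log2fc": np.log2(fc)}, index=ds.values.index)


def p_values(ds: ExpressionDataset, test: str = "student") -> pd.DataFrame:
    """Two-sample t-test on log2 intensities, per gene.

    ``test="student"`` (default) assumes a shared noise variance across the
    two groups; ``test="welch"`` drops that assumption at the cost of an
    estimated df. Returns columns ``p_value`` and ``testable``. Genes are testable only
    when both groups have >=2 samples. Degenerate zero-variance genes with
    equal group means produce NaN from the test and are mapped to p = 1
    (no evidence against the null); zero variance with unequal means yields
    p = 0.
    """
    origin = ds.values[ds.origin_samples]
    target = ds.values[ds.target_samples]
    testable = origin.shape[1] >= 2 and target.shape[1] >= 2
    n_genes = len(ds.values.index)
    if not testable:
        log.info("%s: %d vs %d samples, p-values unavailable", ds.dataset_id,
                 origin.shape[1], target.shape[1])
        return pd.DataFrame(
            {"p_value": np.full(n_genes, np.nan), "testable": False}, index=ds.values.index
        )
    lo = np.log2(np.maximum(origin.to_numpy(), np.finfo(float).tiny))
    lt = np.log2(np.maximum(target.to_numpy(), np.finfo(float).tiny))
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes trip scipy's catastrophic-cancellation warning;
        # they are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(lt, lo, axis=1, equal_var=(test == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance: equal means -> NaN -> 1; unequal -> p = 0
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"p_value": p, "testable": True}, index=ds.values.index)


def call_directions(de: pd.DataFrame, th: DEThresholds = DEThresholds()) -> pd.Series:
    """Three-way direction call from fold change and p-value.

    Testable genes: up/down when p <= p_max with the sign of log2fc, else
    none. Untestable genes: in fc_only mode, called by
    max(fc, 1/fc) >= fc_min alone; in strict mode, always none.
    """
    direction = pd.Series(NONE, index=de.index, dtype=object)
    testable = de["testable"].to_numpy(dtype=bool)
    sig = testable & (de["p_value"].to_numpy() <= th.p_max)
    log2fc = de["log2fc"].to_numpy()
    direction[sig & (log2fc > 0)] = UP
    direction[sig & (log2fc < 0)] = DOWN
    if th.single_sample_mode == "fc_only":
        fc = de["fc_linear"].to_numpy()
        mag = np.maximum(fc, 1.0 / fc)
        passed = ~testable & (mag >= th.fc_min)
        direction[passed & (log2fc > 0)] = UP
        direction[passed & (log2fc < 0)] = DOWN
    return direction


def differential_expression(ds: ExpressionDataset, th: DEThresholds = DEThresholds()) -> DEResult:
    """Full per-dataset DE: fold change, p-values and direction calls."""
    table = fold_change(ds).join(p_values(ds, test=th.test))
    table["direction"] = call_directions(table, th)
    return DEResult(dataset_id=ds.dataset_id, table=table)
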