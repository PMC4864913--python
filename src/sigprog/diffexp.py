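"""Stage 1: paired differential-expression testing and filtering.

Probes are tested one at a time with a paired-sample t test on the per-pair
log2 differences (treatment minus control). Multiple testing is controlled by
bounding the *expected number of false positives*: with ``N`` probes tested,
declaring significance at ``p < E_fp / N`` yields ``E_fp`` false positives in
expectation under the global null. Two further biological filters follow the
significance cut: a minimum mean expression level (the probe must average at
least ``min_mean_log2`` in at least one condition) and a minimum effect size
(``|mean_diff| >= min_abs_diff`` log2 units; the default of 1 corresponds to
a two-fold change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigError, ExpressionMatrix, FLOAT_FMT

#: smallest positive double, reported for zero-variance probes with a
#: nonzero mean difference
TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class DiffExpConfig:
    """Thresholds for the three-step filter cascade.

    Attributes
    ----------
    e_fp
        Expected number of false positives tolerated across all probes;
        the significance threshold is ``e_fp / N``.
    min_mean_log2
        Minimum mean log2 expression required in at least one condition.
    min_abs_diff
        Minimum absolute paired mean log2 difference (1 = fold change 2).
    """

    e_fp: float = 1.0
    min_mean_log2: float = 6.0
    min_abs_diff: float = 1.0

    def __post_init__(self) -> None:
        if self.e_fp <= 0:
            raise ConfigError("e_fp must be positive")
        if self.min_abs_diff < 0:
            raise ConfigError("min_abs_diff must be non-negative")


@dataclass
class DiffExpRecord:
    probe_id: str
    mean_control: float
    mean_treatment: float
    mean_diff: float
    t_stat: float
    p_value: float
    direction: int
    passed_significance: bool
    passed_expression: bool
    passed_foldchange: bool
    degenerate: bool = False

    @property
    def passed_all(self) -> bool:
        return self.passed_significance and self.passed_expression and self.passed_foldchange


def significance_threshold(e_fp: float, n: int) -> float:
    """p-value cut-off ``e_fp / n`` bounding expected false positives.

    With ``e_fp = 1`` and ``n = 22277`` probes this is about 4.5e-5.
    """
    if n < 1:
        raise ConfigError("n must be a positive integer")
    if e_fp <= 0:
        raise ConfigError("e_fp must be positive")
    return e_fp / n


def paired_t_test(x_control: np.ndarray, x_treatment: np.ndarray) -> tuple[float, float, float]:
    """Paired t test on aligned per-pair values.

    Returns ``(t_stat, two_sided_p, mean_diff)`` where
    ``t = mean(d) / (sd(d) / sqrt(n))`` on the differences
    ``d = treatment - control`` with ``n - 1`` degrees of freedom.

    Degenerate inputs (all differences identical, so ``sd(d) = 0``) return
    ``(0, 1, 0)`` when the common difference is zero and
    ``(inf * sign, TINY_P, mean_diff)`` otherwise.
    """
    d = np.asarray(x_treatment, dtype=float) - np.asarray(x_control, dtype=float)
    if d.ndim != 1 or d.size < 3:
        raise ConfigError("paired t test requires at least 3 aligned pairs")
    n = d.size
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_diff == 0.0:
            return 0.0, 1.0, 0.0
        return float(np.sign(mean_diff)) * np.inf, TINY_P, mean_diff
    t = mean_diff / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return float(t), min(p, 1.0), mean_diff


def run_diffexp(em: ExpressionMatrix, cfg: DiffExpConfig | None = None) -> list[DiffExpRecord]:
    """Test every probe and populate the three filter flags.

    One record is returned per probe, in the matrix's probe order.
    Zero-variance probes are flagged ``degenerate`` rather than dropped.
    """
    cfg = cfg or DiffExpConfig()
    ctrl, trt, _ = em.paired_arrays()
    n_pairs = ctrl.shape[1]
    if n_pairs < 3:
        raise ConfigError("paired t test requires at least 3 pairs")
    d = trt - ctrl
    mean_diff = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / (sd / np.sqrt(n_pairs))
    p = 2.0 * stats.t.sf(np.abs(t), n_pairs - 1)

    degenerate = sd == 0.0
    zero_null = degenerate & (mean_diff == 0.0)
    t = np.where(zero_null, 0.0, t)
    p = np.where(zero_null, 1.0, p)
    shifted = degenerate & (mean_diff != 0.0)
    t = np.where(shifted, np.sign(mean_diff) * np.inf, t)
    p = np.where(shifted, TINY_P, p)
    p = np.minimum(p, 1.0)

    thr = significance_threshold(cfg.e_fp, em.n_probes)
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    records = []
    for i, probe in enumerate(em.probe_ids):
        records.append(
            DiffExpRecord(
                probe_id=probe,
                mean_control=float(mean_c[i]),
                mean_treatment=float(mean_t[i]),
                mean_diff=float(mean_diff[i]),
                t_stat=float(t[i]),
                p_value=float(p[i]),
                direction=1 if mean_diff[i] >= 0 else -1,
                passed_significance=bool(p[i] < thr),
                passed_expression=bool(max(mean_c[i], mean_t[i]) >= cfg.min_mean_log2),
                passed_foldchange=bool(abs(mean_diff[i]) >= cfg.min_abs_diff),
                degenerate=bool(degenerate[i]),
            )
        )
    return records


def cascade_counts(records: list[DiffExpRecord]) -> dict[str, int]:
    """Probe counts surviving each successive filter step.

    The filters are applied in the order significance -> expression ->
    fold change; since the flags are conjunctive the final count does not
    depend on the order, but the cascade mirrors the reporting convention.
    """
    sig = [r for r in records if r.passed_significance]
    expr = [r for r in sig if r.passed_expression]
    fc = [r for r in expr if r.passed_foldchange]
    return {
        "total": len(records),
        "significant": len(sig),
        "after_expression": len(expr),
        "after_foldchange": len(fc),
    }


def select_deg(records: list[DiffExpRecord]) -> list[DiffExpRecord]:
    """Keep exactly the records passing all three filters (order preserved)."""
    return [r for r in records if r.passed_all]


# ---------------------------------------------------------------------------
# tabular round-trip
# ---------------------------------------------------------------------------

_COLUMNS = [
    "probe_id", "mean_control", "mean_treatment", "mean_diff", "t_stat",
    "p_value", "direction", "passed_significance", "passed_expression",
    "passed_foldchange", "degenerate",
]


def records_to_frame(records: list[DiffExpRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])


def write_diffexp_table(records: list[DiffExpRecord], path) -> None:
    df = records_to_frame(records)
    for c in ("passed_significance", "passed_expression", "passed_foldchange", "degenerate"):
        df[c] = df[c].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_diffexp_table(path) -> list[DiffExpRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DiffExpRecord(
                probe_id=str(row.probe_id),
                mean_control=float(row.mean_control),
                mean_treatment=float(row.mean_treatment),
                mean_diff=float(row.mean_diff),
                t_stat=float(row.t_stat),
                p_value=float(row.p_value),
                direction=int(row.direction),
                passed_significance=bool(row.passed_significance),
                passed_expression=bool(row.passed_expression),
                passed_foldchange=bool(row.passed_foldchange),
                degenerate=bool(row.degenerate),
            )
        )
    return records
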