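"""Summary statistics for editing experiments.

Editing purity is the fraction of edited reads that carry the intended edit:
``purity = 100 * c / (c + i)`` with c the correct-edit frequency and i the
unwanted-indel frequency.  The relative editing-purity ratio compares a
variant to a named reference enzyme, ``(c_v / c_r) / (i_v / i_r)``.
Replicates are summarized as mean +/- SEM (sample SD over sqrt(n)), and group
comparisons use the two-tailed unpaired Student's t-test (pooled variance;
Welch available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = float("nan")


@dataclass(frozen=True)
class ReplicateSet:
    """Per-replicate percent frequencies for one variant/site."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError(f"replicate set '{self.label}' is empty")
        if any(not math.isfinite(v) or v < 0 for v in self.values):
            raise ValueError(f"replicate set '{self.label}' has invalid values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PurityReport:
    label: str
    freq_correct: float
    freq_indel: float

    @property
    def purity(self) -> float:
        return editing_purity(self.freq_correct, self.freq_indel)


def editing_purity(freq_correct: float, freq_indel: float) -> float:
    """Percent of edited reads carrying the correct edit: 100*c/(c+i).

    Undefined (NaN, never 0 or 100) when both inputs are zero.
    """
    if freq_correct < 0 or freq_indel < 0:
        raise ValueError("frequencies must be >= 0")
    denom = freq_correct + freq_indel
    if denom == 0:
        return MISSING
    return 100.0 * freq_correct / denom


def relative_purity_ratio(variant: PurityReport, reference: PurityReport) -> float:
    """(c_v/c_r) / (i_v/i_r): fold-improvement in edit:indel balance over the
    reference enzyme.  Infinite when the variant produced no indels (callers
    should report such replicates as excluded rather than average them in)."""
    if reference.freq_correct <= 0 or reference.freq_indel <= 0:
        raise ValueError(
            f"reference '{reference.label}' must have positive correct and indel frequencies"
        )
    if variant.freq_indel == 0:
        return math.inf
    return (variant.freq_correct / reference.freq_correct) / (
        variant.freq_indel / reference.freq_indel
    )


def aggregate_mean_sem(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, SEM (sample SD with n-1 denominator over sqrt(n); NaN for n=1),
    and n."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot aggregate an empty value list")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, MISSING, 1
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, sem, int(vals.size)


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def _values(group) -> np.ndarray:
    if isinstance(group, ReplicateSet):
        return np.asarray(group.values, dtype=float)
    return np.asarray(list(group), dtype=float)


def t_test_two_tailed(a, b, welch: bool = False) -> TTestResult:
    """Two-tailed unpaired Student's t-test (pooled variance by default).

    ``a`` and ``b`` are ReplicateSets or plain sequences with n >= 2 each.
    Returns (t, df, p); df = n_a + n_b - 2 for the pooled test.
    """
    x, y = _values(a), _values(b)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test requires at least 2 values per group")
    if welch:
        res = stats.ttest_ind(x, y, equal_var=False)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
    na, nb = len(x), len(y)
    df = na + nb - 2
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        t = 0.0 if x.mean() == y.mean() else math.inf * np.sign(x.mean() - y.mean())
    else:
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return TTestResult(float(t), float(df), p)


def summary_report(
    table: pd.DataFrame,
    reference: str,
    ratio_mode: str = "per_site",
    min_n_ttest: int = 3,
) -> pd.DataFrame:
    """Per variant x site summary of an editing experiment.

    ``table`` needs one row per replicate with columns ``variant``, ``site``,
    ``freq_correct``, ``freq_indel`` (percent).  For each variant x site the
    report gives mean +/- SEM of both frequencies, purity of the mean
    frequencies, the relative purity ratio versus ``reference`` and the
    pooled-variance t-test against the reference (computed when both groups
    have at least ``min_n_ttest`` replicates).

    ``ratio_mode='per_site'`` (default) computes one ratio per variant
    replicate against the reference's per-site mean frequencies, then
    aggregates mean +/- SEM; replicates with zero indel frequency are
    excluded from the ratio mean and counted in ``ratio_n_excluded``.
    ``ratio_mode='pooled'`` reports the single ratio of mean frequencies.
    Output ordering is deterministic (reference first, then by variant, site).
    """
    required = {"variant", "site", "freq_correct", "freq_indel"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"summary table missing columns {sorted(missing)}")
    if ratio_mode not in ("per_site", "pooled"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    variants = sorted(table["variant"].unique())
    if reference not in variants:
        raise ValueError(f"reference variant '{reference}' not present in table")

    ref_by_site: dict[str, tuple[float, float, np.ndarray, np.ndarray]] = {}
    for site, sub in table[table["variant"] == reference].groupby("site"):
        ref_by_site[site] = (
            float(sub["freq_correct"].mean()),
            float(sub["freq_indel"].mean()),
            sub["freq_correct"].to_numpy(float),
            sub["freq_indel"].to_numpy(float),
        )

    rows = []
    ordered = [reference] + [v for v in variants if v != reference]
    for variant in ordered:
        for site in sorted(table.loc[table["variant"] == variant, "site"].unique()):
            sub = table[(table["variant"] == variant) & (table["site"] == site)]
            c = sub["freq_correct"].to_numpy(float)
            i = sub["freq_indel"].to_numpy(float)
            mean_c, sem_c, n = aggregate_mean_sem(c)
            mean_i, sem_i, _ = aggregate_mean_sem(i)
            row = {
                "variant": variant,
                "site": site,
                "n": n,
                "mean_correct": mean_c,
                "sem_correct": sem_c,
                "mean_indel": mean_i,
                "sem_indel": sem_i,
                "purity": editing_purity(mean_c, mean_i),
            }
            ref = ref_by_site.get(site)
            if ref is None:
                row.update(
                    ratio_mean=MISSING, ratio_sem=MISSING, ratio_n=0, ratio_n_excluded=0,
                    p_correct=MISSING, p_indel=MISSING,
                )
                rows.append(row)
                continue
            c_r, i_r, ref_c, ref_i = ref
            ref_report = PurityReport(reference, c_r, i_r)
            if ratio_mode == "pooled":
                ratio = relative_purity_ratio(PurityReport(variant, mean_c, mean_i), ref_report)
                row.update(
                    ratio_mean=ratio if math.isfinite(ratio) else MISSING,
                    ratio_sem=MISSING,
                    ratio_n=1,
                    ratio_n_excluded=0 if math.isfinite(ratio) else 1,
                )
            else:
                ratios = [
                    relative_purity_ratio(PurityReport(variant, cv, iv), ref_report)
                    for cv, iv in zip(c, i)
                ]
                finite = [r for r in ratios if math.isfinite(r)]
                if finite:
                    r_mean, r_sem, r_n = aggregate_mean_sem(finite)
                else:
                    r_mean, r_sem, r_n = MISSING, MISSING, 0
                row.update(
                    ratio_mean=r_mean,
                    ratio_sem=r_sem,
                    ratio_n=r_n,
                    ratio_n_excluded=len(ratios) - len(finite),
                )
            if variant != reference and n >= min_n_ttest and len(ref_c) >= min_n_ttest:
                row["p_correct"] = t_test_two_tailed(c, ref_c).p
                row["p_indel"] = t_test_two_tailed(i, ref_i).p
            else:
                row["p_correct"] = MISSING
                row["p_indel"] = MISSING
            rows.append(row)
    return pd.DataFrame(rows)


def write_report_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_report_json(report: pd.DataFrame, path) -> None:
    import json

    with open(path, "w") as out:
        json.dump(report.to_dict(orient="records"), out, indent=1, sort_keys=True,
                  default=float)
        out.write("\n")
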