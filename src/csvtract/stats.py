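"""Group statistics on tract proportions.

Per subject and hemisphere, the proportion of CSv streamlines assigned to each
tract; across subjects, mean +/- SEM, a two-sided one-sample t-test of each
proportion against zero, Bonferroni-corrected significance (family alpha 0.05
over 7 tracts -> per-test alpha reported as 0.007), and hemisphere-presence
counts (how many subject-hemispheres contain at least one streamline of the
tract).  Zero-variance cells — e.g. a tract absent in every subject — are
reported as "test not performed" rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import UNCATEGORISED, ClassificationResult
from .io import ValidationError


@dataclass
class SubjectTractProportions:
    subject_id: str
    hemisphere: str
    n_csv_streamlines: int
    proportions: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_csv_streamlines < 0:
            raise ValidationError("streamline count must be >= 0")
        if not self.degenerate:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-12:
                raise ValidationError(f"proportions sum to {total}, expected 1")


def tract_proportions(result: ClassificationResult, subject_id: str,
                      hemisphere: str) -> SubjectTractProportions:
    """Per-tract proportion = tract count / total CSv streamline count.

    A hemisphere with zero CSv streamlines yields all-zero proportions with
    the ``degenerate`` flag set.
    """
    total = result.n_streamlines
    counts = dict(result.counts)
    counts.setdefault(UNCATEGORISED, 0)
    if total == 0:
        return SubjectTractProportions(subject_id, hemisphere, 0,
                                       {k: 0.0 for k in counts}, counts=counts,
                                       degenerate=True)
    props = {k: v / total for k, v in counts.items()}
    return SubjectTractProportions(subject_id, hemisphere, total, props,
                                   counts=counts)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    ci_low: float
    ci_high: float
    p: float
    tested: bool
    reason: str = ""


def one_sample_ttest(values: Sequence[float], mu0: float = 0.0,
                     confidence: float = 0.95) -> TTestResult:
    """Two-sided one-sample t-test with a matching two-sided CI.

    t = (mean - mu0) / (sd / sqrt(n)) with the n-1 sd; CI = mean +/-
    t_crit(df, confidence) * SEM.  Samples with zero variance (all values
    identical) cannot be tested and are flagged, mirroring tracts that carry
    no streamlines in any subject.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two observations")
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    df = n - 1
    # identical observations: sd may be a rounding-level positive number
    if sd == 0.0 or np.all(x == x[0]):
        return TTestResult(t=np.nan, df=df, ci_low=mean, ci_high=mean,
                           p=np.nan, tested=False, reason="zero variance")
    sem = sd / np.sqrt(n)
    t = (mean - mu0) / sem
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, df)
    return TTestResult(t=float(t), df=df, ci_low=float(mean - tcrit * sem),
                       ci_high=float(mean + tcrit * sem), p=float(p), tested=True)


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 7) -> float:
    """Per-test alpha = family alpha / number of tests (0.05 / 7 -> 0.00714...,
    conventionally reported as 0.007)."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0.0 < family_alpha < 1.0:
        raise ValidationError("family_alpha must lie in (0, 1)")
    return family_alpha / m


@dataclass
class GroupStatsResult:
    table: pd.DataFrame               # one row per tract x hemisphere
    alpha_per_test: float
    presence: dict[str, tuple[int, int]]   # tract -> (k hemispheres with >=1, n)
    confidence: float = 0.95


def summarize_group(subjects: Sequence[SubjectTractProportions],
                    family_alpha: float = 0.05, m_tests: int = 7,
                    confidence: float = 0.95) -> GroupStatsResult:
    """Across-subject summary per tract and hemisphere.

    Every hemisphere present must be covered by the same subjects; SEM is the
    n-1 sample sd over sqrt(n); significance is assessed at
    ``bonferroni_alpha(family_alpha, m_tests)``.  Presence counts pool both
    hemispheres: k of n subject-hemisphere cells holding >= 1 streamline.
    """
    if not subjects:
        raise ValidationError("no subjects provided")
    hemis = sorted({s.hemisphere for s in subjects})
    by_hemi = {h: [s for s in subjects if s.hemisphere == h] for h in hemis}
    n_per = {h: len(v) for h, v in by_hemi.items()}
    if len(set(n_per.values())) > 1:
        raise ValidationError(f"hemisphere coverage mismatch: {n_per}")
    if min(n_per.values()) < 2:
        raise ValidationError("need >= 2 subjects per hemisphere")

    tracts = sorted({t for s in subjects for t in s.proportions})
    alpha = bonferroni_alpha(family_alpha, m_tests)
    rows = []
    presence: dict[str, tuple[int, int]] = {}
    for tract in tracts:
        k = sum(1 for s in subjects if s.counts.get(tract, 0) >= 1)
        presence[tract] = (k, len(subjects))
    for hemi in hemis:
        group = by_hemi[hemi]
        for tract in tracts:
            vals = np.array([s.proportions.get(tract, 0.0) for s in group])
            n = len(vals)
            mean = vals.mean()
            sd = vals.std(ddof=1)
            sem = sd / np.sqrt(n)
            res = one_sample_ttest(vals, mu0=0.0, confidence=confidence)
            rows.append({
                "tract": tract, "hemisphere": hemi, "n": n,
                "mean": mean, "sem": sem, "t": res.t, "df": res.df,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                "tested": res.tested,
                "significant": bool(res.tested and res.p < alpha),
                "presence_k": presence[tract][0],
                "presence_n": presence[tract][1],
            })
    return GroupStatsResult(table=pd.DataFrame(rows), alpha_per_test=alpha,
                            presence=presence, confidence=confidence)


def plot_group_proportions(result: GroupStatsResult, path=None, exclude=(UNCATEGORISED,)):
    """Bar plot of mean tract proportions with +/- 1 SEM error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table[~result.table["tract"].isin(exclude)]
    tracts = sorted(tab["tract"].unique())
    hemis = sorted(tab["hemisphere"].unique())
    x = np.arange(len(tracts))
    width = 0.8 / max(len(hemis), 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, hemi in enumerate(hemis):
        sub = tab[tab["hemisphere"] == hemi].set_index("tract").reindex(tracts)
        ax.bar(x + i * width, sub["mean"], width, yerr=sub["sem"], capsize=3,
               label=hemi)
    ax.set_xticks(x + width * (len(hemis) - 1) / 2)
    ax.set_xticklabels(tracts, rotation=45, ha="right")
    ax.set_ylabel("proportion of CSv streamlines")
    ax.legend(title="hemisphere")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
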