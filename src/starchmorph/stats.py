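"""Group statistics: one-way ANOVA, Tukey HSD with compact letter display,
and Pearson genotype-phenotype correlation.

A summary-statistic input mode (group mean, SEM, n) exists so published
tables can be re-analysed without raw data: the within-group sum of squares
is reconstructed from ``SD = SEM * sqrt(n)``, which is algebraically exact
for the F statistic and for Tukey's pooled variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "CLDResult",
    "as_summaries",
    "one_way_anova",
    "tukey_cld",
    "pearson_correlation",
]


@dataclass
class GroupSummary:
    """Mean +/- SEM summary of one group of n replicates."""

    label: str
    mean: float
    sem: float
    n: int
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float


@dataclass
class CLDResult:
    """Compact letter display: groups sharing a letter are not
    significantly different pairwise at ``alpha``."""

    letters: dict[str, str]
    alpha: float
    p_matrix: np.ndarray
    labels: list[str]


def as_summaries(groups) -> list[GroupSummary]:
    """Normalize raw-value groups or summaries to :class:`GroupSummary`.

    Accepts a list of ``GroupSummary``, a mapping ``label -> values`` or a
    list of value arrays (labelled g1, g2, ...).
    """
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = []
        for i, g in enumerate(groups):
            if isinstance(g, GroupSummary):
                items.append((g.label, g))
            else:
                items.append((f"g{i + 1}", g))
    out = []
    for label, g in items:
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            v = np.asarray(g, dtype=float)
            if v.size < 2:
                raise ValueError(f"group {label!r}: need n >= 2 raw values")
            sd = v.std(ddof=1)
            out.append(
                GroupSummary(
                    label=label,
                    mean=float(v.mean()),
                    sem=float(sd / np.sqrt(v.size)),
                    n=int(v.size),
                    values=v,
                )
            )
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA from raw values or mean/SEM/n summaries."""
    gs = as_summaries(groups)
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    grand = float(np.sum(ns * means) / ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_b = len(gs) - 1
    df_w = int(ns.sum()) - len(gs)
    if df_w <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_w = ss_within / df_w
    if ms_w == 0 and ss_between == 0:
        raise ValueError("zero total variance")
    if ms_w == 0:
        return AnovaResult(np.inf, 0.0, df_b, df_w, 0.0)
    F = (ss_between / df_b) / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, ms_w)


def _tukey_p_matrix(gs: list[GroupSummary], ms_within: float, df_w: int) -> np.ndarray:
    k = len(gs)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(ms_within / 2.0 * (1.0 / gs[i].n + 1.0 / gs[j].n))
            if se == 0:
                pij = 1.0 if gs[i].mean == gs[j].mean else 0.0
            else:
                q = abs(gs[i].mean - gs[j].mean) / se
                pij = float(sps.studentized_range.sf(q, k, df_w))
            p[i, j] = p[j, i] = pij
    return p


def _insert_absorb(nonsig: np.ndarray) -> list[set[int]]:
    """Insert-and-absorb letter construction from the non-significance
    relation."""
    k = nonsig.shape[0]
    letters: list[set[int]] = [set(range(k))]
    # split any letter containing a significant pair
    changed = True
    while changed:
        changed = False
        for li, members in enumerate(letters):
            ms = sorted(members)
            for ai in range(len(ms)):
                for bi in range(ai + 1, len(ms)):
                    a, b = ms[ai], ms[bi]
                    if not nonsig[a, b]:
                        without_a = members - {a}
                        without_b = members - {b}
                        letters.pop(li)
                        letters.extend([without_a, without_b])
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
    # absorb letters that are subsets of others; drop empties
    letters = [l for l in letters if l]
    letters = [
        l
        for i, l in enumerate(letters)
        if not any(l < other or (l == other and i > j) for j, other in enumerate(letters))
    ]
    return letters


def tukey_cld(groups, alpha: float = 0.05) -> CLDResult:
    """All-pairs Tukey HSD plus an insert-and-absorb compact letter display.

    Deterministic given the input ordering; letter symbols are assigned in
    descending order of group mean so 'a' marks the largest-mean cluster.
    """
    gs = as_summaries(groups)
    res = one_way_anova(gs)
    pmat = _tukey_p_matrix(gs, res.ms_within, res.df_within)
    nonsig = pmat >= alpha
    letter_sets = _insert_absorb(nonsig)
    # order letters by the best (largest) mean they contain
    means = np.array([g.mean for g in gs])
    letter_sets.sort(key=lambda s: (-max(means[list(s)]), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, str] = {g.label: "" for g in gs}
    for sym, members in zip(alphabet, letter_sets):
        for m in members:
            assigned[gs[m].label] += sym
    return CLDResult(
        letters=assigned, alpha=alpha, p_matrix=pmat, labels=[g.label for g in gs]
    )


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n
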