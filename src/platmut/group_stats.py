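"""Group-level mutation-burden statistics.

Compares treated clone groups against matched mock-treated groups: mean
per-genome mutation counts with standard errors, excess burdens over mock,
relative mutagenicity percentages, unpaired t-tests and dose-trend flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MUTATION_TYPES = ("SNV", "INS", "DEL")

DOSE_ORDER = ("mock", "IC25", "IC50")


@dataclass(frozen=True)
class TreatmentGroup:
    """One treatment arm: a drug at a dose tier in one cell line.

    ``dose`` is one of ``mock``, ``IC25``, ``IC50`` (IC25/IC50 are the
    equitoxic concentrations allowing 75%/50% survival; here they are pure
    labels).  Each sample id belongs to exactly one group.
    """

    drug: str
    dose: str
    cell_line: str
    samples: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))

    @property
    def name(self) -> str:
        return f"{self.drug}_{self.dose}"

    @property
    def is_mock(self) -> bool:
        return self.dose == "mock" or self.drug == "mock"


@dataclass
class BurdenSummary:
    """Per-sample counts, per-group means/SEMs/excesses, and pairwise tests."""

    per_sample: pd.DataFrame   # sample, drug, dose, cell_line, type, count
    groups: pd.DataFrame       # drug, dose, cell_line, type, n, mean, sem, excess_over_mock
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)  # vs matched mock


def _sample_counts(calls: pd.DataFrame, samples: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for s in samples:
        sub = calls[calls["sample"] == s] if len(calls) else calls
        for t in MUTATION_TYPES:
            n = int((sub["type"] == t).sum()) if len(sub) else 0
            rows.append({"sample": s, "type": t, "count": n})
    return pd.DataFrame(rows)


def burden_table(calls: pd.DataFrame, groups: list[TreatmentGroup]) -> BurdenSummary:
    """Per-group burden means, SEMs and excesses over the matched mock group.

    Every sample in ``groups`` contributes a count for each mutation type
    (zero if it has no calls).  The excess of a treated group is its mean
    minus the mean of the mock group of the same cell line; if that mock
    group is absent the excess is reported missing.  Treated groups are also
    tested against their mock with a two-sided unpaired t-test.
    """
    seen: dict[str, str] = {}
    for g in groups:
        for s in g.samples:
            if s in seen:
                raise ValueError(f"sample {s!r} assigned to both {seen[s]} and {g.name}")
            seen[s] = g.name

    per_sample_parts = []
    for g in groups:
        cnt = _sample_counts(calls, g.samples)
        cnt["drug"], cnt["dose"], cnt["cell_line"] = g.drug, g.dose, g.cell_line
        per_sample_parts.append(cnt)
    per_sample = pd.concat(per_sample_parts, ignore_index=True)

    mock_means: dict[tuple[str, str], float] = {}
    mock_counts: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        if g.is_mock:
            sub = per_sample[per_sample["sample"].isin(g.samples)]
            for t in MUTATION_TYPES:
                vals = sub.loc[sub["type"] == t, "count"].to_numpy(float)
                mock_means[(g.cell_line, t)] = float(vals.mean())
                mock_counts[(g.cell_line, t)] = vals

    grows, trows = [], []
    for g in groups:
        sub = per_sample[per_sample["sample"].isin(g.samples)]
        for t in MUTATION_TYPES:
            vals = sub.loc[sub["type"] == t, "count"].to_numpy(float)
            n = len(vals)
            mean = float(vals.mean()) if n else math.nan
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            excess = math.nan
            if not g.is_mock and (g.cell_line, t) in mock_means:
                excess = mean - mock_means[(g.cell_line, t)]
            grows.append({"drug": g.drug, "dose": g.dose, "cell_line": g.cell_line,
                          "type": t, "n": n, "mean": mean, "sem": sem,
                          "excess_over_mock": excess})
            if not g.is_mock and (g.cell_line, t) in mock_counts:
                mock_vals = mock_counts[(g.cell_line, t)]
                if n >= 2 and len(mock_vals) >= 2:
                    tstat, df, p = unpaired_t(vals, mock_vals)
                    trows.append({"drug": g.drug, "dose": g.dose,
                                  "cell_line": g.cell_line, "type": t,
                                  "t": tstat, "df": df, "p": p})
    return BurdenSummary(per_sample=per_sample,
                         groups=pd.DataFrame(grows),
                         tests=pd.DataFrame(trows))


def relative_mutagenicity(excess_drug: float, excess_reference: float) -> tuple[float, int]:
    """Excess burden of a drug as a percentage of a reference drug's excess.

    Returns ``(unrounded_percent, rounded_percent)``; e.g. excesses of 324
    vs 532 give (60.90..., 61).
    """
    if excess_reference <= 0:
        raise ValueError("reference excess must be positive")
    pct = 100.0 * excess_drug / excess_reference
    return pct, int(round(pct))


def unpaired_t(group_a, group_b, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; pooled-variance Student's t by default.

    Returns ``(t, df, p)``.  Degenerate zero-variance inputs are resolved
    explicitly: equal means give ``(0, df, 1)``, unequal means give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, df, 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def dose_trend(summary: BurdenSummary) -> pd.DataFrame:
    """Flag, per (cell line, drug, type), whether mean burden is non-decreasing
    over the dose tiers mock <= IC25 <= IC50.  Missing tiers give a missing flag.
    """
    g = summary.groups
    rows = []
    for cell_line in sorted(g["cell_line"].unique()):
        gc = g[g["cell_line"] == cell_line]
        drugs = sorted(set(gc.loc[gc["dose"] != "mock", "drug"]) - {"mock"})
        for drug in drugs:
            for t in MUTATION_TYPES:
                means = []
                ok = True
                for dose in DOSE_ORDER:
                    if dose == "mock":
                        sel = gc[(gc["dose"] == "mock") & (gc["type"] == t)]
                    else:
                        sel = gc[(gc["drug"] == drug) & (gc["dose"] == dose) & (gc["type"] == t)]
                    if len(sel) == 0:
                        ok = False
                        break
                    means.append(float(sel["mean"].iloc[0]))
                monotone = (
                    all(means[i] <= means[i + 1] for i in range(len(means) - 1))
                    if ok else None
                )
                rows.append({"cell_line": cell_line, "drug": drug, "type": t,
                             "monotone_non_decreasing": monotone})
    return pd.DataFrame(rows)
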