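"""Exclusionary screening of cranium-atlas pairs by superimposition RMS.

The screen is deliberately one-sided.  Among superimpositions of bones
known to come from the same individual (matches), the largest observed
RMS defines a threshold; a candidate pair whose RMS exceeds it cannot be
a match and is *excluded*, while anything at or below the threshold stays
*inconclusive* — below the threshold match and mismatch RMS distributions
overlap, so the screen never asserts that two bones belong together.

The module provides the experiment design (every match plus a seeded
random draw of same-sex mismatch combinations), threshold derivation,
per-pair verdicts, the exclusion-rate summary, and the group statistics:
a two-way ANOVA (group x sex, type-II sums of squares for the unbalanced
design) with Levene's test for homoscedasticity and the Jarque-Bera test
for normality per cell.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registration import DistanceSummary, Superimposition

__all__ = [
    "ExperimentDesign",
    "design_experiment",
    "derive_threshold",
    "screen_pair",
    "group_stats",
    "summarize_screening",
    "ExclusionScreen",
    "ScreeningResults",
]

EXCLUDED = "excluded"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ExperimentDesign:
    """The superimposition task list: all matches + sampled same-sex mismatches."""

    match_pairs: tuple[tuple[str, str], ...]
    mismatch_pairs: tuple[tuple[str, str], ...]
    seed: int

    @property
    def n_tasks(self) -> int:
        return len(self.match_pairs) + len(self.mismatch_pairs)


def design_experiment(individuals: Sequence[tuple[str, str]],
                      n_mismatch_per_sex: int, seed: int = 0) -> ExperimentDesign:
    """Build the match/mismatch superimposition plan.

    Parameters
    ----------
    individuals : sequence of (id, sex)
        Sex must be "female" or "male" for mismatch sampling.
    n_mismatch_per_sex : int
        Ordered mismatch pairs to draw uniformly without replacement
        within each sex (mismatches are kept sex-homogeneous so sex can
        enter the group statistics as a clean factor).

    With 46 individuals (26 F, 20 M) and 130 mismatches per sex this
    yields 46 + 260 = 306 superimposition tasks.
    """
    ids = [i for i, _ in individuals]
    if len(set(ids)) != len(ids):
        raise ValueError("individual ids must be unique")
    if n_mismatch_per_sex < 0:
        raise ValueError("n_mismatch_per_sex must be non-negative")
    match_pairs = tuple((i, i) for i in ids)
    rng = np.random.default_rng(seed)
    mismatch: list[tuple[str, str]] = []
    present = [s for s in ("female", "male") if any(sx == s for _, sx in individuals)]
    for sex in present:
        members = [i for i, s in individuals if s == sex]
        n = len(members)
        available = n * (n - 1)
        if n_mismatch_per_sex > available:
            raise ValueError(
                f"requested {n_mismatch_per_sex} {sex} mismatches but only "
                f"{available} ordered same-sex pairs exist ({n} individuals)"
            )
        pairs = [(a, b) for a in members for b in members if a != b]
        idx = rng.choice(available, size=n_mismatch_per_sex, replace=False) if available else []
        mismatch.extend(pairs[i] for i in sorted(idx))
    return ExperimentDesign(match_pairs=match_pairs, mismatch_pairs=tuple(mismatch),
                            seed=seed)


def _rms_of(item) -> float:
    if isinstance(item, Superimposition):
        return item.summary.rms
    if isinstance(item, DistanceSummary):
        return item.rms
    return float(item)


def derive_threshold(match_summaries: Iterable) -> float:
    """Exclusion threshold: the maximum RMS observed among known matches."""
    values = [_rms_of(m) for m in match_summaries]
    if not values:
        raise ValueError("need at least one match summary")
    return float(max(values))


def screen_pair(rms: float, threshold: float) -> str:
    """Verdict for one candidate pair.

    Strictly above the threshold -> ``excluded``; otherwise
    ``inconclusive``.  A tie stays inconclusive: exclusion must be
    conservative, and by design no verdict ever affirms a match.
    """
    if rms < 0:
        raise ValueError("rms must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return EXCLUDED if rms > threshold else INCONCLUSIVE


def group_stats(data: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-way ANOVA (group x sex) with distributional diagnostics.

    Expects columns ``rms``, ``group`` and ``sex``.  Uses type-II sums of
    squares (the 46-match / 260-mismatch design is unbalanced) with the
    interaction term included and reported.  Levene's test checks
    homoscedasticity across the group x sex cells; the Jarque-Bera test
    checks normality within each cell.  If a factor has an empty level
    combination the model degrades to a one-way ANOVA on ``group`` with a
    warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"rms", "group", "sex"} - set(data.columns)
    if required:
        raise ValueError(f"data missing columns {sorted(required)}")
    cells = data.groupby(["group", "sex"], observed=True)["rms"]
    cell_sizes = cells.size()
    n_groups = data["group"].nunique()
    n_sexes = data["sex"].nunique()
    two_way = len(cell_sizes) == n_groups * n_sexes and n_sexes > 1
    if two_way:
        if (cell_sizes < 2).any():
            raise ValueError("each group x sex cell needs at least 2 observations")
    elif (data.groupby("group")["rms"].size() < 2).any():
        raise ValueError("each group needs at least 2 observations")

    if not two_way and n_sexes > 1:
        warnings.warn("incomplete group x sex grid; falling back to one-way ANOVA",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if two_way:
            model = smf.ols("rms ~ C(group) * C(sex)", data=data).fit()
        else:
            model = smf.ols("rms ~ C(group)", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=2)

    if two_way:
        diag_cells = [(f"{g}/{s}", v.to_numpy()) for (g, s), v in cells]
    else:
        diag_cells = [(str(g), v.to_numpy())
                      for g, v in data.groupby("group", observed=True)["rms"]]
    levene = stats.levene(*[v for _, v in diag_cells])
    jb = {
        name: {"statistic": float(r.statistic), "p_value": float(r.pvalue)}
        for name, v in diag_cells
        for r in [stats.jarque_bera(v)]
    }

    def term(name: str) -> dict | None:
        if name not in anova.index:
            return None
        row = anova.loc[name]
        return {"F": float(row["F"]), "p_value": float(row["PR(>F)"]),
                "df": float(row["df"])}

    return {
        "anova": {
            "group": term("C(group)"),
            "sex": term("C(sex)"),
            "interaction": term("C(group):C(sex)"),
        },
        "levene": {"statistic": float(levene.statistic), "p_value": float(levene.pvalue)},
        "jarque_bera": jb,
        "alpha": alpha,
        "design": "two-way" if two_way else "one-way",
        "anova_table": anova,
    }


class ExclusionScreen:
    """Model object for the RMS-based exclusion screen.

    Built from superimposition outcomes — a frame with columns ``rms``
    (mm), ``group`` ("match"/"mismatch") and optionally ``sex`` — and
    fitted by deriving the exclusion threshold from the match group and
    screening every pair against it.

    Examples
    --------
    >>> screen = ExclusionScreen(rms_frame)        # doctest: +SKIP
    >>> res = screen.fit()                         # doctest: +SKIP
    >>> res.threshold, res.exclusion_fraction_mismatch   # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame):
        missing = {"rms", "group"} - set(data.columns)
        if missing:
            raise ValueError(f"data missing columns {sorted(missing)}")
        bad = set(data["group"].unique()) - {"match", "mismatch"}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        if (data["rms"] < 0).any():
            raise ValueError("rms values must be non-negative")
        self.data = data.reset_index(drop=True)
        self.n_match = int((data["group"] == "match").sum())
        self.n_mismatch = int((data["group"] == "mismatch").sum())

    @classmethod
    def from_superimpositions(cls, results: Iterable[Superimposition],
                              sexes: dict[str, str] | None = None) -> "ExclusionScreen":
        rows = []
        for s in results:
            row = {"oc_id": s.oc_id, "c1_id": s.c1_id, "rms": s.summary.rms,
                   "group": s.label}
            if sexes is not None:
                row["sex"] = sexes.get(s.oc_id, "unknown")
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def fit(self, threshold: float | None = None, alpha: float = 0.05,
            with_group_stats: bool | None = None) -> "ScreeningResults":
        """Derive (or accept) the threshold and screen every pair.

        ``threshold=None`` derives it as the maximum match RMS; passing a
        value screens against a previously established threshold.  Group
        statistics are computed when both groups and a ``sex`` column are
        present (or as a one-way comparison without sex).
        """
        if threshold is None:
            if self.n_match == 0:
                raise ValueError("cannot derive a threshold without match pairs")
            threshold = derive_threshold(self.data.loc[self.data["group"] == "match", "rms"])
        verdicts = self.data.copy()
        verdicts["verdict"] = [screen_pair(r, threshold) for r in verdicts["rms"]]

        mis = verdicts[verdicts["group"] == "mismatch"]
        if len(mis):
            exclusion_fraction = float((mis["verdict"] == EXCLUDED).mean())
        else:
            exclusion_fraction = float("nan")
            warnings.warn("no mismatch pairs: exclusion fraction undefined", stacklevel=2)

        stats_block = None
        run_stats = with_group_stats
        if run_stats is None:
            run_stats = self.n_match > 0 and self.n_mismatch > 0
        if run_stats:
            frame = self.data.copy()
            if "sex" not in frame.columns:
                frame["sex"] = "unknown"
            try:
                stats_block = group_stats(frame, alpha=alpha)
            except ValueError as exc:
                warnings.warn(f"group statistics unavailable: {exc}", stacklevel=2)
        return ScreeningResults(self, threshold=float(threshold), verdicts=verdicts,
                                exclusion_fraction_mismatch=exclusion_fraction,
                                group_statistics=stats_block)


@dataclass
class ScreeningResults:
    """Fitted exclusion screen: threshold, verdicts, rates and statistics."""

    model: ExclusionScreen
    threshold: float
    verdicts: pd.DataFrame
    exclusion_fraction_mismatch: float
    group_statistics: dict | None = None

    @property
    def n_excluded_matches(self) -> int:
        v = self.verdicts
        return int(((v["group"] == "match") & (v["verdict"] == EXCLUDED)).sum())

    def to_json(self, path=None) -> str:
        payload = {
            "threshold_mm": self.threshold,
            "n_match": self.model.n_match,
            "n_mismatch": self.model.n_mismatch,
            "exclusion_fraction_mismatch": self.exclusion_fraction_mismatch,
            "verdicts": self.verdicts.drop(columns=["sex"], errors="ignore")
                                     .to_dict(orient="records"),
        }
        if self.group_statistics is not None:
            gs = {k: v for k, v in self.group_statistics.items() if k != "anova_table"}
            payload["group_statistics"] = gs
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot_rms(self, ax=None):
        """Scatter of RMS by group with the threshold line (screening overview)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for group, marker, color in (("match", "o", "tab:green"),
                                     ("mismatch", "s", "tab:red")):
            sub = self.verdicts[self.verdicts["group"] == group]
            ax.scatter(np.arange(len(sub)), sub["rms"], marker=marker, s=18,
                       label=group, color=color, alpha=0.7)
        ax.axhline(self.threshold, ls="--", color="k",
                   label=f"threshold {self.threshold:.2f} mm")
        ax.set_xlabel("superimposition index")
        ax.set_ylabel("RMS (mm)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Exclusionary screening of cranium-atlas superimpositions",
            f"  matches: {self.model.n_match}, mismatches: {self.model.n_mismatch}",
            f"  exclusion threshold (max match RMS): {self.threshold:.3f} mm",
        ]
        if np.isnan(self.exclusion_fraction_mismatch):
            lines.append("  mismatch exclusion fraction: n.a. (no mismatches)")
        else:
            lines.append(
                f"  mismatches excluded: {100 * self.exclusion_fraction_mismatch:.1f}%"
            )
        lines.append(f"  matches excluded: {self.n_excluded_matches} (0 by construction "
                     "when the threshold is derived from these matches)")
        gs = self.group_statistics
        if gs is not None:
            g = gs["anova"]["group"]
            lines.append(f"  ANOVA ({gs['design']}): group F = {g['F']:.2f}, "
                         f"p = {g['p_value']:.3g}")
            s = gs["anova"]["sex"]
            if s is not None:
                lines.append(f"           sex   F = {s['F']:.2f}, p = {s['p_value']:.3g}")
            lines.append(f"  Levene homoscedasticity p = {gs['levene']['p_value']:.3g}")
        lines.append("Verdicts are exclusion-only: pairs at or below the threshold "
                     "remain inconclusive, never confirmed matches.")
        return "\n".join(lines)


def summarize_screening(results: Iterable[Superimposition] | pd.DataFrame,
                        threshold: float | None = None,
                        sexes: dict[str, str] | None = None) -> ScreeningResults:
    """Functional wrapper: screen superimposition outcomes and summarise.

    Accepts either ``Superimposition`` objects or a frame with ``rms`` and
    ``group`` columns; ``threshold=None`` derives the max-of-matches
    threshold from the data.
    """
    if isinstance(results, pd.DataFrame):
        screen = ExclusionScreen(results)
    else:
        screen = ExclusionScreen.from_superimpositions(results, sexes=sexes)
    return screen.fit(threshold=threshold)
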