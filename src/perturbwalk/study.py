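"""Cohort-level analysis: the falls-history group comparison as a model object.

:class:`PerturbationStudy` takes tidy per-participant tables (MoS of the
labeled steps around each analyzed perturbation, and recovery-step counts
per perturbation) and ``fit()`` runs the full battery:

* per perturbation, a mixed two-way repeated-measures ANOVA with group
  (Falls / NoFalls) and step (Base, Pre, Post1-8) as factors;
* Dunnett many-to-one comparisons of each step against Base within group;
* Sidak-adjusted between-group comparisons per step;
* Mann-Whitney U on recovery-step counts per perturbation;
* Friedman across perturbations within each group (falling back to pairwise
  Wilcoxon signed-rank tests when a group's blocks are incomplete).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import stats as st

__all__ = ["PerturbationStudy", "PerturbationStudyResults"]

STEP_ORDER = ["Base", "Pre"] + [f"Post{m}" for m in range(1, 9)]


class PerturbationStudy:
    """Group comparison of perturbation responses.

    Parameters
    ----------
    mos_long : DataFrame with columns participant, group, perturbation,
        step (Base/Pre/Post1-8), mos.
    recovery : DataFrame with columns participant, group, perturbation,
        recovery_steps.  Optional; recovery-step tests are skipped without it.
    alpha : significance level used in the summary.
    """

    def __init__(
        self,
        mos_long: pd.DataFrame | None = None,
        recovery: pd.DataFrame | None = None,
        alpha: float = 0.05,
    ):
        if mos_long is None and recovery is None:
            raise ValueError("need at least one of mos_long / recovery")
        self.mos_long = mos_long
        self.recovery = recovery
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, mos_long, recovery=None, **kw) -> "PerturbationStudy":
        return cls(mos_long=mos_long, recovery=recovery, **kw)

    def fit(self, correction: bool = False, seed: int = 0) -> "PerturbationStudyResults":
        anovas: dict = {}
        dunnett: dict = {}
        sidak: dict = {}
        if self.mos_long is not None:
            for pert, sub in self.mos_long.groupby("perturbation"):
                anovas[pert] = st.mixed_anova(
                    sub, dv="mos", within="step", between="group",
                    subject="participant", correction=correction,
                )
                wide = sub.pivot_table(
                    index=["participant", "group"], columns="step", values="mos"
                ).reset_index()
                for g, gsub in wide.groupby("group"):
                    cols = ["Base"] + [c for c in STEP_ORDER[1:] if c in gsub]
                    dunnett[(pert, g)] = st.dunnett_vs_control(
                        gsub[cols], control="Base", seed=seed
                    )
                # between-group per step: Welch t per step, Sidak family
                praw, steps_present = [], []
                for step in [s for s in STEP_ORDER if s in set(sub["step"])]:
                    vals = sub[sub["step"] == step]
                    gl = vals[vals["group"] == "Falls"]["mos"]
                    gn = vals[vals["group"] == "NoFalls"]["mos"]
                    from scipy.stats import ttest_ind

                    praw.append(float(ttest_ind(gl, gn, equal_var=False).pvalue))
                    steps_present.append(step)
                sidak[pert] = pd.DataFrame(
                    {
                        "step": steps_present,
                        "p_unadjusted": praw,
                        "p_adjusted": st.sidak_adjust(praw),
                    }
                ).set_index("step")

        mwu: dict = {}
        friedman: dict = {}
        wilcoxon_pairs: dict = {}
        if self.recovery is not None:
            for pert, sub in self.recovery.groupby("perturbation"):
                gl = sub[sub["group"] == "Falls"]["recovery_steps"].to_numpy()
                gn = sub[sub["group"] == "NoFalls"]["recovery_steps"].to_numpy()
                if gl.size and gn.size:
                    mwu[pert] = st.mann_whitney_u(gl, gn)
            for g, gsub in self.recovery.groupby("group"):
                block = gsub.pivot_table(
                    index="participant", columns="perturbation",
                    values="recovery_steps",
                )
                if block.isna().any().any():
                    pairs = {}
                    for a, b in combinations(block.columns, 2):
                        sub2 = block[[a, b]].dropna()
                        if len(sub2) >= 2:
                            res = st.wilcoxon_signed_rank(
                                sub2[a].to_numpy(), sub2[b].to_numpy()
                            )
                            pairs[(a, b)] = (res.W, res.p)
                    wilcoxon_pairs[g] = pairs
                else:
                    friedman[g] = st.friedman(block.to_numpy())

        return PerturbationStudyResults(
            study=self, anovas=anovas, dunnett=dunnett, sidak=sidak,
            mann_whitney=mwu, friedman=friedman, wilcoxon_pairs=wilcoxon_pairs,
        )


@dataclass
class PerturbationStudyResults:
    """Fitted group-comparison battery with a printable summary."""

    study: PerturbationStudy
    anovas: dict
    dunnett: dict
    sidak: dict
    mann_whitney: dict
    friedman: dict
    wilcoxon_pairs: dict

    def summary(self) -> str:
        a = self.study.alpha
        lines = ["Perturbation-response group comparison", "=" * 40]
        for pert, res in self.anovas.items():
            lines.append(f"\nPerturbation {pert}: mixed ANOVA (group x step)")
            for name in ("group", "step", "interaction"):
                row = res.effect(name)
                mark = " *" if row["p"] < a else ""
                lines.append(
                    f"  {name:12s} F({row['df1']:.0f}, {row['df2']:.0f}) = "
                    f"{row['F']:.2f}, p = {row['p']:.4f}{mark}"
                )
        if self.mann_whitney:
            lines.append("\nRecovery steps, Falls vs NoFalls (Mann-Whitney):")
            for pert, (u, p) in sorted(self.mann_whitney.items()):
                mark = " *" if p < a else ""
                lines.append(f"  perturbation {pert}: U = {u:.1f}, p = {p:.3f}{mark}")
        for g, (stat, p) in self.friedman.items():
            mark = " *" if p < a else ""
            lines.append(
                f"\n{g}: Friedman across perturbations: chi2 = {stat:.2f}, "
                f"p = {p:.4f}{mark}"
            )
        for g, pairs in self.wilcoxon_pairs.items():
            lines.append(f"\n{g}: pairwise Wilcoxon (incomplete blocks):")
            for (x, y), (w, p) in pairs.items():
                mark = " *" if p < a else ""
                lines.append(f"  {x} vs {y}: W = {w:.1f}, p = {p:.3f}{mark}")
        return "\n".join(lines)

    def recovery_means(self) -> pd.DataFrame:
        """Group mean recovery steps per perturbation (may be non-integer)."""
        if self.study.recovery is None:
            raise ValueError("no recovery table in this study")
        return (
            self.study.recovery.groupby(["group", "perturbation"])["recovery_steps"]
            .mean()
            .unstack()
        )

    def plot_recovery(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = self.recovery_means()
        for g, row in means.iterrows():
            ax.plot(row.index, row.values, "o-", label=g)
        ax.set_xlabel("perturbation")
        ax.set_ylabel("mean recovery steps")
        ax.set_ylim(0, 8)
        ax.legend()
        return ax

    def plot_mos(self, pert, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.study.mos_long[self.study.mos_long["perturbation"] == pert]
        for g, gsub in sub.groupby("group"):
            means = gsub.groupby("step")["mos"].mean().reindex(STEP_ORDER)
            ax.plot(STEP_ORDER, means.values, "o-", label=g)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_ylabel("anteroposterior MoS (m)")
        ax.set_title(f"perturbation {pert}")
        ax.tick_params(axis="x", rotation=45)
        ax.legend()
        return ax
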