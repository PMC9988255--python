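"""Planned orthogonal contrasts for mixed (between x within) factorial designs.

Analyses are sets of 1-df planned contrasts with the error rate controlled
*per contrast* at alpha (no familywise correction) — deliberately different
from omnibus-ANOVA practice, and stated prominently for that reason.

The univariate approach: each within-subject contrast is reduced to one
score per subject (the within-weights applied to that subject's responses);
a between-weighted combination of cell means of those scores is tested
against the pooled within-cell variance of the scores, F(1, N - J) with J
the number of between cells (e.g. F(1, 53) for 57 subjects in 4 cells).
With two-level within factors no sphericity machinery is needed.  Simple
effects re-test one factor inside a single level of another against the
*pooled* error term from the full design, so df2 is constant across the
report.

Unbalanced cells use unweighted (cell-mean) weighting for the contrast
estimate; the error term pools within-cell variance across all cells.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "SimpleEffectResult",
    "validate_table",
    "build_contrast_set",
    "linear_trend_weights",
    "test_contrast",
    "simple_effects",
    "analyze_design",
]

logger = logging.getLogger(__name__)


@dataclass
class ContrastSpec:
    """One planned 1-df contrast.

    ``between_weights`` maps each between-subject cell (a tuple of factor
    levels, in ``between_factors`` order) to a real weight; weights sum to
    zero for contrasts involving between factors and are all equal for
    pure within contrasts.  ``within_weights`` maps within levels to
    weights; sum-to-zero for within-involving contrasts, all equal
    (subject mean) for pure between contrasts.
    """

    name: str
    between_factors: tuple[str, ...]
    within_factor: str
    between_weights: Mapping[tuple, float]
    within_weights: Mapping[object, float]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.between_weights.values()):
            raise ValueError(f"contrast {self.name}: between weights all zero")
        if not any(w != 0 for w in self.within_weights.values()):
            raise ValueError(f"contrast {self.name}: within weights all zero")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def involves_between(self) -> bool:
        return abs(sum(self.between_weights.values())) < 1e-12

    @property
    def involves_within(self) -> bool:
        return abs(sum(self.within_weights.values())) < 1e-12

    def cell_weight_vector(self) -> np.ndarray:
        """Flattened cell x within-level weight vector (orthogonality checks)."""
        return np.array([
            bw * ww
            for _, bw in sorted(self.between_weights.items())
            for _, ww in sorted(self.within_weights.items(), key=lambda kv: str(kv[0]))
        ])


@dataclass
class ContrastResult:
    """F test of one planned contrast."""

    name: str
    ss_contrast: float
    df1: int
    df2: int
    F: float
    p: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_record(self) -> dict:
        return {
            "contrast": self.name,
            "ss": self.ss_contrast,
            "df1": self.df1,
            "df2": self.df2,
            "F": self.F,
            "p": self.p,
            "significant": self.significant,
        }


@dataclass
class SimpleEffectResult:
    """Simple-effect F: one factor tested within a level of another."""

    interaction: str
    condition_factor: str
    condition_level: object
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_record(self) -> dict:
        return {
            "interaction": self.interaction,
            "condition_factor": self.condition_factor,
            "condition_level": self.condition_level,
            "effect": self.effect,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "significant": self.significant,
        }


def validate_table(
    table: pd.DataFrame,
    between_factors: Sequence[str],
    within_factor: str,
    response: str = "response",
) -> None:
    """Check the long-format factorial-table invariants.

    Every subject must appear in exactly one between-subject cell and have
    exactly one finite response at every within level.
    """
    required = {"subject", response, within_factor, *between_factors}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table[response].to_numpy(dtype=float))):
        raise ValueError("responses must be finite")
    levels = list(pd.unique(table[within_factor]))
    per_subj = table.groupby("subject", sort=False)
    for subj, g in per_subj:
        cells = g[list(between_factors)].drop_duplicates()
        if len(cells) != 1:
            raise ValueError(f"subject {subj} appears in more than one between cell")
        if sorted(map(str, g[within_factor])) != sorted(map(str, levels)):
            raise ValueError(
                f"subject {subj} lacks a complete set of within-level responses"
            )


def linear_trend_weights(levels: Sequence) -> dict:
    """Centered linear-trend weights over ordered within levels.

    The 1-df contrast for 'response increases across days': weights are the
    centered session indices, e.g. days 1..4 -> (-1.5, -0.5, 0.5, 1.5).
    """
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels for a trend")
    w = np.arange(k, dtype=float) - (k - 1) / 2.0
    return dict(zip(levels, w))


def build_contrast_set(
    between_factors: Mapping[str, Sequence],
    within_factors: Mapping[str, Sequence],
    alpha: float = 0.05,
) -> list[ContrastSpec]:
    """The full orthogonal contrast set for a 2^k between x 2 within design.

    Returns one contrast per non-empty subset of the factors: every
    between main effect, the within main effect, and all interactions —
    2^m - 1 contrasts for m factors, mutually orthogonal by construction
    (+-1 product coding under equal-n weighting).

    Only 2-level factors are in scope; a >2-level factor raises
    ``NotImplementedError`` (use :func:`linear_trend_weights` to build
    trend contrasts by hand for ordered factors like training day).
    """
    for name, levels in itertools.chain(between_factors.items(), within_factors.items()):
        if len(levels) != 2:
            raise NotImplementedError(
                f"factor {name!r} has {len(levels)} levels; only 2-level factors "
                "are supported in automatic contrast-set construction"
            )
    if len(within_factors) > 1:
        raise NotImplementedError("at most one within-subject factor is supported")

    bf_names = list(between_factors)
    cells = list(itertools.product(*(between_factors[f] for f in bf_names)))
    within_name = next(iter(within_factors), "_none")
    within_levels = list(next(iter(within_factors.values()), ("_only",)))

    all_factors = bf_names + (list(within_factors) if within_factors else [])
    specs = []
    for r in range(1, len(all_factors) + 1):
        for subset in itertools.combinations(all_factors, r):
            bw = {}
            for cell in cells:
                w = 1.0
                for f, lev in zip(bf_names, cell):
                    if f in subset:
                        w *= 1.0 if lev == between_factors[f][0] else -1.0
                bw[cell] = w
            if within_name in subset:
                ww = {within_levels[0]: 1.0, within_levels[1]: -1.0}
            else:
                ww = {lev: 1.0 / len(within_levels) for lev in within_levels}
            specs.append(ContrastSpec(
                name=" x ".join(subset),
                between_factors=tuple(bf_names),
                within_factor=within_name,
                between_weights=bw,
                within_weights=ww,
                alpha=alpha,
            ))

    # orthogonality is structural; verify anyway (equal-n cell weighting)
    for a, b in itertools.combinations(specs, 2):
        dot = float(a.cell_weight_vector() @ b.cell_weight_vector())
        if abs(dot) > 1e-10:
            raise AssertionError(f"contrasts {a.name} and {b.name} are not orthogonal")
    return specs


def _subject_scores(
    table: pd.DataFrame, spec: ContrastSpec, response: str = "response"
) -> pd.DataFrame:
    """One row per subject: between cell + within-weighted contrast score."""
    bf = list(spec.between_factors)
    wf = spec.within_factor
    df = table.copy()
    if wf in df.columns:
        wmap = {k: float(v) for k, v in spec.within_weights.items()}
        unknown = set(df[wf].unique()) - set(wmap)
        if unknown:
            raise ValueError(f"within levels {sorted(map(str, unknown))} have no weight")
        df["_w"] = df[wf].map(wmap)
    else:
        if spec.involves_within:
            raise ValueError(f"table has no within column {wf!r}")
        df["_w"] = 1.0
    df["_wy"] = df["_w"] * df[response]
    g = df.groupby(["subject"] + bf, sort=False, observed=True)["_wy"].sum()
    out = g.reset_index().rename(columns={"_wy": "score"})
    return out


def _pooled_error(scores: pd.DataFrame, bf: list[str]) -> tuple[float, int]:
    """Pooled within-cell variance of subject scores and its df (N - J)."""
    groups = scores.groupby(bf, sort=False, observed=True)["score"]
    n_total = len(scores)
    n_cells = groups.ngroups
    df2 = n_total - n_cells
    if df2 < 1:
        raise ValueError(
            f"error df = {df2} (N={n_total}, cells={n_cells}); need more than one "
            "subject per cell"
        )
    sse = float(sum(((g - g.mean()) ** 2).sum() for _, g in groups))
    return sse / df2, df2


def _contrast_f(
    scores: pd.DataFrame,
    bf: list[str],
    cell_weights: Mapping[tuple, float],
    mse: float,
    df2: int,
    alpha: float,
    name: str,
) -> ContrastResult:
    """1-df F for a between-weighted combination of cell means of scores."""
    means = scores.groupby(bf, sort=False, observed=True)["score"].agg(["mean", "count"])
    L = 0.0
    denom = 0.0
    for cell, w in cell_weights.items():
        if w == 0:
            continue
        key = cell if len(bf) > 1 else cell[0]
        if key not in means.index:
            raise ValueError(f"contrast {name}: between cell {cell} is empty")
        row = means.loc[key]
        L += w * float(row["mean"])
        denom += w * w / float(row["count"])
    ss = L * L / denom
    if mse <= 0:
        warnings.warn(
            f"contrast {name}: zero error variance; F reported as +inf", stacklevel=2
        )
        f_val = float("inf") if ss > 0 else 0.0
        p = 0.0 if ss > 0 else 1.0
    else:
        f_val = ss / mse
        p = float(stats.f.sf(f_val, 1, df2))
    return ContrastResult(
        name=name, ss_contrast=ss, df1=1, df2=df2, F=f_val, p=p, alpha=alpha
    )


def test_contrast(
    table: pd.DataFrame, spec: ContrastSpec, response: str = "response"
) -> ContrastResult:
    """Test one planned contrast on a long-format factorial table.

    For a pure between contrast on two groups the resulting F equals the
    square of the pooled-variance two-sample t statistic.
    """
    scores = _subject_scores(table, spec, response)
    bf = list(spec.between_factors)
    mse, df2 = _pooled_error(scores, bf)
    return _contrast_f(
        scores, bf, spec.between_weights, mse, df2, spec.alpha, spec.name
    )


def simple_effects(
    table: pd.DataFrame,
    interaction: ContrastSpec,
    condition_on: str,
    response: str = "response",
) -> list[SimpleEffectResult]:
    """Decompose a significant interaction into simple effects.

    For each level of ``condition_on``, tests the remaining factor(s)'
    contrast restricted to that level, against the pooled error term and
    df from the *full* design — hence the constant df2 across the report.

    ``condition_on`` may be a between factor (e.g. the within-subject
    devaluation effect tested separately in CTL and lesioned groups) or
    the within factor (the between contrast tested at each within level).
    """
    bf = list(interaction.between_factors)
    wf = interaction.within_factor
    name = interaction.name
    alpha = interaction.alpha
    results: list[SimpleEffectResult] = []

    if condition_on in bf:
        idx = bf.index(condition_on)
        scores = _subject_scores(table, interaction, response)
        mse, df2 = _pooled_error(scores, bf)
        effect_name = " x ".join(
            p for p in name.split(" x ") if p != condition_on
        ) or wf
        for level in pd.unique(table[condition_on]):
            cw = {
                cell: w for cell, w in interaction.between_weights.items()
                if cell[idx] == level
            }
            at_level = {c: abs(w) for c, w in cw.items()}
            # remaining-factor signs within this slice; pure-within remainder
            # reduces to the (equal-weight) mean score at the level
            rem = {c: w for c, w in cw.items()}
            s = sum(rem.values())
            use = rem if abs(s) < 1e-12 else at_level
            res = _contrast_f(scores, bf, use, mse, df2, alpha,
                              f"{effect_name} | {condition_on}={level}")
            results.append(SimpleEffectResult(
                interaction=name, condition_factor=condition_on,
                condition_level=level, effect=effect_name,
                F=res.F, df1=1, df2=res.df2, p=res.p, alpha=alpha,
            ))
    elif condition_on == wf:
        effect_name = " x ".join(p for p in name.split(" x ") if p != wf)
        for level in pd.unique(table[wf]):
            sub = table[table[wf] == level]
            slice_spec = ContrastSpec(
                name=f"{effect_name} | {wf}={level}",
                between_factors=interaction.between_factors,
                within_factor=wf,
                between_weights=interaction.between_weights,
                within_weights={level: 1.0},
                alpha=alpha,
            )
            scores = _subject_scores(sub, slice_spec, response)
            mse, df2 = _pooled_error(scores, bf)
            res = _contrast_f(scores, bf, interaction.between_weights, mse, df2,
                              alpha, slice_spec.name)
            results.append(SimpleEffectResult(
                interaction=name, condition_factor=wf, condition_level=level,
                effect=effect_name, F=res.F, df1=1, df2=res.df2, p=res.p,
                alpha=alpha,
            ))
    else:
        raise ValueError(
            f"condition factor {condition_on!r} is not part of interaction {name!r}"
        )
    return results


def analyze_design(
    table: pd.DataFrame,
    between_factors: Mapping[str, Sequence],
    within_factors: Mapping[str, Sequence],
    alpha: float = 0.05,
    simple_effect_rules: Mapping[str, str] | None = None,
    response: str = "response",
) -> dict:
    """Run the full planned-contrast analysis and triggered simple effects.

    For every significant interaction, simple effects are run conditioning
    on the factor named in ``simple_effect_rules`` (keyed by interaction
    name); by default, a two-way between x within interaction conditions
    on its between factor.

    Returns a dict with ``contrasts`` (list of :class:`ContrastResult`),
    ``simple_effects`` (list of :class:`SimpleEffectResult`), and
    DataFrame views under ``contrast_table`` / ``simple_effect_table``.
    """
    within_name = next(iter(within_factors), None)
    validate_table(table, list(between_factors), within_name, response)
    specs = build_contrast_set(between_factors, within_factors, alpha)
    results = [test_contrast(table, s, response) for s in specs]

    rules = dict(simple_effect_rules or {})
    se_results: list[SimpleEffectResult] = []
    for spec, res in zip(specs, results):
        parts = spec.name.split(" x ")
        if len(parts) < 2 or not res.significant:
            continue
        cond = rules.get(spec.name)
        if cond is None:
            bt = [p for p in parts if p in between_factors]
            if len(parts) == 2 and within_name in parts and len(bt) == 1:
                cond = bt[0]
            else:
                continue
        se_results.extend(simple_effects(table, spec, cond, response))

    return {
        "contrasts": results,
        "simple_effects": se_results,
        "contrast_table": pd.DataFrame([r.to_record() for r in results]),
        "simple_effect_table": pd.DataFrame([r.to_record() for r in se_results]),
        "alpha": alpha,
    }
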