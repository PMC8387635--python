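"""Rating-scale statistics: condition means, t-tests, CIs, Hedges's g.

Each rating scale (SAM 1-9, vocal self-rating 1-4, third-party 1-10) is
compared between the two elicitation scenarios per emotion and item. The
design is within-subject, so a paired t-test is the default; the effect
size is Hedges's g with small-sample correction

    g = J · |mean(x) − mean(y)| / s_pooled,   J = 1 − 3 / (4·(n_x+n_y−2) − 1)

reported as a magnitude, with the paired-difference standardized effect
(d_z) carried alongside. The 95% CI is on the raw mean difference, oriented
so the difference is non-negative (matching how the comparisons are
conventionally printed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfiniteEffectError, MissingDataError

SCALE_BOUNDS: dict[str, tuple[float, float]] = {
    "SAM": (1, 9),
    "self_vocal": (1, 4),
    "third_party": (1, 10),
}

SAM_ITEMS = ("pleasure", "activation", "dominance")
VOCAL_ITEMS = ("coherence", "breath", "resonance", "intonation",
               "language", "musicality", "expression")
EMOTIONS = ("negative", "neutral", "positive")
SCENARIOS = ("self", "vr")

RATING_COLUMNS = ("subject", "scenario", "emotion", "scale", "item", "score")


@dataclass
class StatRow:
    """One comparison row: condition means, p, 95% CI, effect sizes."""

    item: str
    emotion: str
    mean_self: float
    mean_vr: float
    p: float
    ci_low: float
    ci_high: float
    g: float        # pooled-SD Hedges's g, magnitude (the table analogue)
    g_dz: float     # paired-difference standardized effect, magnitude
    paired: bool


def hedges_g(x, y) -> float:
    """Bias-corrected standardized mean difference (magnitude)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    df = nx + ny - 2
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = abs(x.mean() - y.mean())
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        raise InfiniteEffectError(
            "zero pooled variance with unequal means: effect size unbounded"
        )
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(J * diff / np.sqrt(pooled_var))


def validate_rating_table(table: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise MissingDataError(f"rating table lacks columns {missing}")
    for scale, grp in table.groupby("scale"):
        if scale not in SCALE_BOUNDS:
            raise MissingDataError(f"unknown scale {scale!r}")
        lo, hi = SCALE_BOUNDS[scale]
        bad = grp[(grp["score"] < lo) | (grp["score"] > hi)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} scores outside [{lo}, {hi}] for scale {scale!r}"
            )
    dup = table.duplicated(subset=["subject", "scenario", "emotion",
                                   "scale", "item"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate rating cells")


def compare_conditions(table: pd.DataFrame, scale: str, item: str,
                       emotion: str, paired: bool = True) -> StatRow:
    """One Tables-2-4-style comparison of the two scenarios."""
    stratum = table[(table["scale"] == scale) & (table["item"] == item)
                    & (table["emotion"] == emotion)]
    per_scen = {}
    for scen in SCENARIOS:
        sub = stratum[stratum["scenario"] == scen]
        if not len(sub):
            raise MissingDataError(
                f"missing stratum: scale={scale!r} item={item!r} "
                f"emotion={emotion!r} scenario={scen!r}"
            )
        per_scen[scen] = sub.sort_values("subject")
    x = per_scen["self"]["score"].to_numpy(float)
    y = per_scen["vr"]["score"].to_numpy(float)
    mean_self, mean_vr = float(x.mean()), float(y.mean())

    if paired:
        subj_x = per_scen["self"]["subject"].to_numpy()
        subj_y = per_scen["vr"]["subject"].to_numpy()
        if len(x) != len(y) or not np.array_equal(subj_x, subj_y):
            raise MissingDataError(
                "paired comparison requires matched subjects in both scenarios"
            )
        d = x - y
        if mean_self < mean_vr:  # orient difference non-negative for CI
            d = -d
        n = d.size
        se = d.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se))
        if np.allclose(d, 0):
            p, g_dz = 1.0, 0.0
        else:
            p = float(stats.ttest_rel(x, y).pvalue)
            g_dz = float((1 - 3 / (4 * (n - 1) - 1)) * abs(d.mean()) / d.std(ddof=1))
    else:
        diff = abs(mean_self - mean_vr)
        nx, ny = x.size, y.size
        df = nx + ny - 2
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        tcrit = stats.t.ppf(0.975, df)
        ci = (float(diff - tcrit * se), float(diff + tcrit * se))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(stats.ttest_ind(x, y).pvalue)
        g_dz = float("nan")

    g = hedges_g(x, y)
    return StatRow(item, emotion, mean_self, mean_vr, p, ci[0], ci[1],
                   g, g_dz, paired)


def format_p(p: float) -> str:
    return "p < 0.01" if p < 0.01 else f"p = {p:.2f}"


def build_tables(table: pd.DataFrame, paired: bool = True
                 ) -> dict[str, pd.DataFrame]:
    """The three formatted comparison tables (SAM 3x3, vocal 7x3, third-party 7x3).

    Rows are items; for each emotion there is a (Self, VR, p, ES) column
    block, mirroring the printed layout.
    """
    if not len(table):
        raise MissingDataError("empty rating table: no design cells present")
    validate_rating_table(table)
    layouts = {"SAM": SAM_ITEMS, "self_vocal": VOCAL_ITEMS,
               "third_party": VOCAL_ITEMS}
    missing_cells = []
    out: dict[str, pd.DataFrame] = {}
    for scale, items in layouts.items():
        records = {}
        for item in items:
            row = {}
            for emo in EMOTIONS:
                try:
                    sr = compare_conditions(table, scale, item, emo, paired)
                except MissingDataError:
                    missing_cells.append((scale, item, emo))
                    continue
                row[(emo, "Self")] = round(sr.mean_self, 2)
                row[(emo, "VR")] = round(sr.mean_vr, 2)
                row[(emo, "p")] = format_p(sr.p)
                row[(emo, "ES")] = round(sr.g, 2)
            records[item] = row
        df = pd.DataFrame.from_dict(records, orient="index")
        df.index.name = "item"
        out[scale] = df
    if missing_cells:
        raise MissingDataError(f"incomplete design; missing cells: {missing_cells}")
    return out
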