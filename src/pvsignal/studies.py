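"""Seeded simulation studies: operating characteristics of the detectors.

These functions run many replicates of the synthetic generator's
count-level path and summarize detection and false-positive rates for the
consensus rule and the sex-stratified modified ROR.  They are the package's
own validation studies; tests and the reproduction script call them with
fixed seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .signals import vectorized_consensus
from .synthetic import SyntheticConfig, _draw_distinct, _weights, simulate_counts


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def planted_recovery(
    planted: tuple[tuple[str, float], ...],
    n_replicates: int = 200,
    seed: int = 0,
    n_target_cases: int = 2000,
    n_background_cases: int = 50000,
) -> pd.DataFrame:
    """Fraction of replicates in which each planted PT is consensus-flagged.

    Returns one row per planted PT with its multiplier, mean observed ``a``
    and the detection fraction.
    """
    cfg = SyntheticConfig(
        n_target_cases=n_target_cases,
        n_background_cases=n_background_cases,
        planted_signals=planted,
    )
    pts = list(cfg.catalog["pt"])
    idx = [pts.index(pt) for pt, _ in planted]
    hits = np.zeros(len(planted))
    a_sum = np.zeros(len(planted))
    for rng in _child_rngs(seed, n_replicates):
        df = simulate_counts(cfg, rng)
        flags = vectorized_consensus(df["a"], df["b"], df["c"], df["d"])
        hits += flags["consensus"][idx]
        a_sum += df["a"].to_numpy()[idx]
    return pd.DataFrame(
        {
            "pt": [pt for pt, _ in planted],
            "multiplier": [m for _, m in planted],
            "mean_a": a_sum / n_replicates,
            "detection_rate": hits / n_replicates,
        }
    )


def null_false_positive_rates(
    n_replicates: int = 50,
    seed: int = 0,
    n_target_cases: int = 2000,
    n_background_cases: int = 50000,
) -> pd.Series:
    """Per-method fraction of terms flagged under the null (no planted
    effects), pooled over replicates."""
    cfg = SyntheticConfig(
        n_target_cases=n_target_cases, n_background_cases=n_background_cases
    )
    totals = {m: 0 for m in ("ror", "mhra", "bcpnn", "mgps", "consensus")}
    n_terms = 0
    for rng in _child_rngs(seed, n_replicates):
        df = simulate_counts(cfg, rng)
        flags = vectorized_consensus(df["a"], df["b"], df["c"], df["d"])
        n_terms += len(df)
        for m in totals:
            totals[m] += int(flags[m].sum())
    return pd.Series({m: v / n_terms for m, v in totals.items()})


def _sex_arm_counts(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-PT female and male event counts for one target cohort draw."""
    f, m, u = cfg.sex_mix
    sexes = rng.choice(3, size=cfg.n_target_cases, p=[f, m, u])
    n_f = int((sexes == 0).sum())
    n_m = int((sexes == 1).sum())
    counts_f, _ = _draw_distinct(rng, n_f, cfg.events_lambda, _weights(cfg, True, True))
    counts_m, _ = _draw_distinct(rng, n_m, cfg.events_lambda, _weights(cfg, True, False))
    return counts_f, counts_m


def _sex_directions(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Direction labels (1=F, -1=M, 0=none) for per-PT female/male counts,
    vectorizing the modified-ROR decision rule."""
    b = a.sum() - a
    d = c.sum() - c
    with np.errstate(divide="ignore", invalid="ignore"):
        n = a + b + c + d
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(denom > 0, (a * d - b * c) ** 2 * n / denom, np.nan)
        p = _stats.chi2.sf(chi2, df=1)
        ror = np.where((b > 0) & (c > 0), (a * d) / (b * c), np.nan)
    out = np.zeros(len(a), dtype=int)
    sig = (p < 0.05) & np.isfinite(ror) & (a > 0) & (c > 0) & (d > 0) & (b > 0)
    out[sig & (ror > 1)] = 1
    out[sig & (ror < 1)] = -1
    return out


def sex_null_calibration(
    n_replicates: int = 200, seed: int = 0, n_target_cases: int = 2000
) -> float:
    """Fraction of both-sex PTs assigned a direction under a null cohort
    (no sex effect); nominally ~5% from the chi-square threshold."""
    cfg = SyntheticConfig(n_target_cases=n_target_cases)
    called = 0
    eligible = 0
    for rng in _child_rngs(seed, n_replicates):
        a, c = _sex_arm_counts(cfg, rng)
        both = (a > 0) & (c > 0)
        called += int((_sex_directions(a, c) != 0)[both].sum())
        eligible += int(both.sum())
    return called / eligible


def sex_planted_power(
    pt: str = "PT_060",
    female_multiplier: float = 3.0,
    n_replicates: int = 200,
    seed: int = 0,
    n_target_cases: int = 2000,
) -> float:
    """Fraction of replicates in which a female-enriched PT is labelled F."""
    cfg = SyntheticConfig(
        n_target_cases=n_target_cases, sex_effects=((pt, female_multiplier),)
    )
    i = list(cfg.catalog["pt"]).index(pt)
    hits = 0
    for rng in _child_rngs(seed, n_replicates):
        a, c = _sex_arm_counts(cfg, rng)
        hits += int(_sex_directions(a, c)[i] == 1)
    return hits / n_replicates
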