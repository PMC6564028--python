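"""Differential-expression calling by two-group test plus threshold filters.

The location test is Welch's unequal-variance t on log2(TPM + 1) — a
deliberate, documented stand-in for transcript-level likelihood-ratio
testing, which needs raw read data and is out of this package's scope.
Raw p-values are corrected with Benjamini–Hochberg (q-values), and genes
are called differentially expressed by the joint threshold rule

    fc_max > min_fc  AND  max(mean TPM) > min_tpm  AND  q < max_q

with all three comparisons strict. Two named profiles ship with the
package: ``ppcd`` (fc > 2, TPM > 15, q < 0.3 — for small, noisy tissue
cohorts, where the loose q guards power at the cost of FDR) and
``cellline`` (fc > 1.5, TPM > 0.6, q < 0.05).

Fold change is the ratio of pseudocounted linear group means,
``fc = (mean_a + pc) / (mean_b + pc)`` with a 0.5 TPM pseudocount, and
``fc_max = max(fc, 1/fc)`` so the threshold is direction-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compendium import ExpressionCompendium
from .genesets import GeneSet

_VAR_FLOOR = 1e-12  # variance floor so zero-variance genes stay defined

#: Named threshold profiles (all bounds strict).
PROFILES: dict[str, "ThresholdProfile"] = {}


@dataclass(frozen=True)
class ThresholdProfile:
    """A named (min_fc, min_tpm, max_q) differential-expression filter."""

    name: str
    min_fc: float
    min_tpm: float
    max_q: float

    def __post_init__(self) -> None:
        if self.min_fc < 1:
            raise ValueError("min_fc must be >= 1")
        if self.min_tpm < 0:
            raise ValueError("min_tpm must be >= 0")
        if not (0 < self.max_q <= 1):
            raise ValueError("max_q must be in (0, 1]")


PROFILES["ppcd"] = ThresholdProfile("ppcd", min_fc=2.0, min_tpm=15.0, max_q=0.3)
PROFILES["cellline"] = ThresholdProfile("cellline", min_fc=1.5, min_tpm=0.6, max_q=0.05)


@dataclass
class DEResultTable:
    """Per-gene statistics plus pass flags under a named threshold profile."""

    table: pd.DataFrame
    profile: ThresholdProfile

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())


def compute_gene_stats(
    compendium: ExpressionCompendium,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene two-group statistics (group_a relative to group_b).

    Returns a DataFrame ordered as the input genes with columns
    ``gene_id, mean_tpm_a, mean_tpm_b, fc, fc_max, direction, p`` and,
    when ``adjust`` is true, BH-adjusted ``q``.

    The p-value comes from Welch's t on log2(TPM + 1); variances are
    floored at 1e-12, so genes with identical values in both groups get
    t = 0, p = 1 rather than NaN.
    """
    for g in (group_a, group_b):
        if g not in compendium.groups():
            raise ValueError(f"group label {g!r} not present in sample sheet")
        if len(compendium.samples_in_group(g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    a = compendium.tpm[compendium.samples_in_group(group_a)].to_numpy(float)
    b = compendium.tpm[compendium.samples_in_group(group_b)].to_numpy(float)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    na, nb = la.shape[1], lb.shape[1]

    ma, mb = la.mean(axis=1), lb.mean(axis=1)
    va = np.maximum(la.var(axis=1, ddof=1), _VAR_FLOOR)
    vb = np.maximum(lb.var(axis=1, ddof=1), _VAR_FLOOR)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    out = pd.DataFrame({
        "gene_id": compendium.gene_ids,
        "mean_tpm_a": mean_a,
        "mean_tpm_b": mean_b,
        "fc": fc,
        "fc_max": np.maximum(fc, 1.0 / fc),
        "direction": np.where(fc >= 1.0, "up", "down"),
        "p": p,
    })
    if adjust:
        out["q"] = bh_adjust(p)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1, returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_de_filters(stats_table: pd.DataFrame, profile: ThresholdProfile) -> DEResultTable:
    """Flag genes passing a threshold profile (all comparisons strict).

    pass <=> fc_max > min_fc  and  max(mean_tpm_a, mean_tpm_b) > min_tpm
             and  q < max_q
    """
    required = {"fc_max", "mean_tpm_a", "mean_tpm_b", "q"}
    missing = required - set(stats_table.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    t = stats_table.copy()
    max_tpm = np.maximum(t["mean_tpm_a"], t["mean_tpm_b"])
    t["pass"] = (
        (t["fc_max"] > profile.min_fc)
        & (max_tpm > profile.min_tpm)
        & (t["q"] < profile.max_q)
    )
    return DEResultTable(table=t, profile=profile)


def de_gene_sets(result: DEResultTable) -> tuple[GeneSet, GeneSet]:
    """Partition passing genes into (up, down) gene sets by direction."""
    t = result.table
    up = t.loc[t["pass"] & (t["direction"] == "up"), "gene_id"]
    down = t.loc[t["pass"] & (t["direction"] == "down"), "gene_id"]
    prov = f"profile={result.profile.name}"
    return (GeneSet("de_up", up, description=prov),
            GeneSet("de_down", down, description=prov))
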