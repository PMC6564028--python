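"""Synthetic-data generators with known ground truth.

Three generators cover every input the analysis stages consume:

* :func:`simulate_compendium` — a two-condition (control vs disease) TPM
  compendium with two disjoint cell-type signature sets and planted
  up-/down-regulated genes whose overlaps with the signatures are exact,
  by construction. This emulates a diseased-endothelium-vs-control study
  in which a subset of epithelial-signature genes is ectopically induced
  and a subset of endothelial-signature genes is lost.
* :func:`simulate_cellline_panel` — a groups x clones panel (e.g. four
  engineered cell lines, three independent clones each) with group-level
  expression shifts, for similarity analytics.
* :func:`simulate_ph_trace` — a BCECF-style intracellular pH time series
  for a lactate perfusion experiment, with analytic kinetic ground truth.

Expression model: baseline log2(TPM) is gene-wise Normal(baseline_log_mean,
baseline_log_sd); planted differential expression multiplies the disease
condition by the planted linear fold; replicate noise is Normal(0,
noise_log_sd) in log2 space. All randomness flows from one
``numpy.random.default_rng(seed)`` per call, so identical configs and seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium
from .genesets import GeneSet


class ConfigurationError(ValueError):
    """A simulation config violates one of its stated constraints."""


@dataclass
class SimulationConfig:
    """Parameters of the planted-signal compendium simulation.

    Defaults mirror the disease-study geometry the package is designed
    around: 429 up- and 378 down-regulated genes, epithelial/endothelial
    signatures of 249 and 108 genes, planted overlaps 75 (up in the
    epithelial signature), 43 (down in the endothelial signature), 3 and 1
    (the two "wrong-direction" overlaps), within a 12,000-gene expressed
    universe. Folds are linear (>1); ``fold_down`` divides.
    """

    universe_size: int = 12_000
    n_up: int = 429
    n_down: int = 378
    sig_epc_size: int = 249
    sig_enc_size: int = 108
    planted_up_in_epc: int = 75
    planted_down_in_enc: int = 43
    planted_up_in_enc: int = 3
    planted_down_in_epc: int = 1
    fold_up: float = 4.0
    fold_down: float = 4.0
    n_replicates_per_group: int = 3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 2.0
    noise_log_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        c = self
        counts = {
            "universe_size": c.universe_size, "n_up": c.n_up, "n_down": c.n_down,
            "sig_epc_size": c.sig_epc_size, "sig_enc_size": c.sig_enc_size,
            "planted_up_in_epc": c.planted_up_in_epc,
            "planted_down_in_enc": c.planted_down_in_enc,
            "planted_up_in_enc": c.planted_up_in_enc,
            "planted_down_in_epc": c.planted_down_in_epc,
            "n_replicates_per_group": c.n_replicates_per_group,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if c.fold_up <= 1 or c.fold_down <= 1:
            raise ConfigurationError("fold_up and fold_down must be > 1")
        if c.n_up + c.n_down > c.universe_size:
            raise ConfigurationError(
                f"n_up + n_down = {c.n_up + c.n_down} exceeds universe_size {c.universe_size}")
        if c.sig_epc_size + c.sig_enc_size > c.universe_size:
            raise ConfigurationError("signature sizes exceed universe_size")
        if c.planted_up_in_epc + c.planted_down_in_epc > c.sig_epc_size:
            raise ConfigurationError(
                "planted_up_in_epc + planted_down_in_epc exceeds sig_epc_size")
        if c.planted_up_in_enc + c.planted_down_in_enc > c.sig_enc_size:
            raise ConfigurationError(
                "planted_up_in_enc + planted_down_in_enc exceeds sig_enc_size")
        if c.planted_up_in_epc + c.planted_up_in_enc > c.n_up:
            raise ConfigurationError("planted up overlaps exceed n_up")
        if c.planted_down_in_enc + c.planted_down_in_epc > c.n_down:
            raise ConfigurationError("planted down overlaps exceed n_down")
        free = c.universe_size - c.sig_epc_size - c.sig_enc_size
        free_de = (c.n_up - c.planted_up_in_epc - c.planted_up_in_enc) + (
            c.n_down - c.planted_down_in_enc - c.planted_down_in_epc)
        if free_de > free:
            raise ConfigurationError(
                f"non-signature DE genes ({free_de}) exceed non-signature universe ({free})")


@dataclass
class TruthTable:
    """Per-gene ground truth of a simulated compendium.

    ``table`` is indexed by gene id with columns ``de_direction``
    (up/down/none, relative to the disease condition), ``in_epc_signature``,
    ``in_enc_signature`` (bool) and ``planted_fold`` (linear, 1 for none).
    """

    table: pd.DataFrame

    def overlap_counts(self) -> dict[str, int]:
        t = self.table
        return {
            "up_in_epc": int(((t.de_direction == "up") & t.in_epc_signature).sum()),
            "down_in_enc": int(((t.de_direction == "down") & t.in_enc_signature).sum()),
            "up_in_enc": int(((t.de_direction == "up") & t.in_enc_signature).sum()),
            "down_in_epc": int(((t.de_direction == "down") & t.in_epc_signature).sum()),
        }

    def genes(self, direction: str) -> frozenset[str]:
        return frozenset(self.table.index[self.table.de_direction == direction])


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[ExpressionCompendium, TruthTable, GeneSet, GeneSet]:
    """Simulate a control-vs-disease compendium with planted structure.

    Returns the compendium, the ground-truth table, and the two signature
    gene sets (epithelial, endothelial). Planted overlap counts between DE
    genes and signatures match the config exactly; with zero noise the
    realized condition-mean TPM ratio of a planted gene equals its fold.
    """
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)

    width = len(str(c.universe_size))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(1, c.universe_size + 1)])

    # One random permutation, then deterministic slicing: every slice below
    # is a uniform random subset and all overlap counts are exact.
    perm = rng.permutation(c.universe_size)
    pos = 0

    def take(n: int) -> np.ndarray:
        nonlocal pos
        out = perm[pos:pos + n]
        pos += n
        return out

    epc_up = take(c.planted_up_in_epc)
    epc_down = take(c.planted_down_in_epc)
    epc_rest = take(c.sig_epc_size - c.planted_up_in_epc - c.planted_down_in_epc)
    enc_up = take(c.planted_up_in_enc)
    enc_down = take(c.planted_down_in_enc)
    enc_rest = take(c.sig_enc_size - c.planted_up_in_enc - c.planted_down_in_enc)
    free_up = take(c.n_up - c.planted_up_in_epc - c.planted_up_in_enc)
    free_down = take(c.n_down - c.planted_down_in_enc - c.planted_down_in_epc)

    epc_idx = np.concatenate([epc_up, epc_down, epc_rest])
    enc_idx = np.concatenate([enc_up, enc_down, enc_rest])
    up_idx = np.concatenate([epc_up, enc_up, free_up])
    down_idx = np.concatenate([epc_down, enc_down, free_down])

    direction = np.full(c.universe_size, "none", dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    planted_fold = np.ones(c.universe_size)
    planted_fold[up_idx] = c.fold_up
    planted_fold[down_idx] = c.fold_down

    base_log2 = rng.normal(c.baseline_log_mean, c.baseline_log_sd, c.universe_size)
    effect_log2 = np.zeros(c.universe_size)
    effect_log2[up_idx] = math.log2(c.fold_up)
    effect_log2[down_idx] = -math.log2(c.fold_down)

    n_rep = c.n_replicates_per_group
    groups = ["control"] * n_rep + ["disease"] * n_rep
    sample_ids = [f"control_{i+1}" for i in range(n_rep)] + [
        f"disease_{i+1}" for i in range(n_rep)]
    log2_mat = np.tile(base_log2[:, None], (1, 2 * n_rep))
    log2_mat[:, n_rep:] += effect_log2[:, None]
    log2_mat += rng.normal(0.0, c.noise_log_sd, log2_mat.shape)
    tpm = np.power(2.0, log2_mat)

    compendium = ExpressionCompendium(
        tpm=pd.DataFrame(tpm, index=gene_ids, columns=sample_ids),
        sample_sheet=pd.DataFrame({
            "sample_id": sample_ids,
            "group": groups,
            "clone": [f"rep{i+1}" for i in range(n_rep)] * 2,
        }),
    )
    truth = TruthTable(pd.DataFrame({
        "de_direction": direction,
        "in_epc_signature": np.isin(np.arange(c.universe_size), epc_idx),
        "in_enc_signature": np.isin(np.arange(c.universe_size), enc_idx),
        "planted_fold": planted_fold,
    }, index=pd.Index(gene_ids, name="gene_id")))
    sig_epc = GeneSet("sig_epc", gene_ids[np.sort(epc_idx)],
                      description="epithelial-specific signature (simulated)")
    sig_enc = GeneSet("sig_enc", gene_ids[np.sort(enc_idx)],
                      description="endothelial-specific signature (simulated)")
    return compendium, truth, sig_epc, sig_enc


def simulate_cellline_panel(
    config: SimulationConfig,
    n_groups: int = 4,
    n_clones: int = 3,
    group_effect_log2: float = 2.0,
    frac_affected: float = 0.1,
) -> ExpressionCompendium:
    """Simulate a cell-line panel of ``n_groups`` x ``n_clones`` samples.

    Each group gets its own Normal(0, group_effect_log2) log2 shift on a
    shared random subset of genes (``frac_affected`` of the universe), so
    within-group correlation exceeds between-group correlation whenever
    the effect dominates the replicate noise. ``group_effect_log2 = 0``
    produces an exchangeable null panel.

    Only the expression-model fields of the config are used here (universe
    size, baseline, noise, seed); the planted-DE fields are ignored, so a
    config need not describe a feasible two-condition experiment.
    """
    if config.universe_size < 1:
        raise ConfigurationError("universe_size must be >= 1")
    if config.noise_log_sd < 0:
        raise ConfigurationError("noise_log_sd must be >= 0")
    if n_groups < 2 or n_clones < 2:
        raise ConfigurationError("n_groups and n_clones must both be >= 2")
    if not (0 <= frac_affected <= 1):
        raise ConfigurationError("frac_affected must be in [0, 1]")
    c = config
    rng = np.random.default_rng(c.seed)
    width = len(str(c.universe_size))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, c.universe_size + 1)]

    base_log2 = rng.normal(c.baseline_log_mean, c.baseline_log_sd, c.universe_size)
    n_affected = int(round(frac_affected * c.universe_size))
    affected = rng.choice(c.universe_size, size=n_affected, replace=False)
    shifts = np.zeros((c.universe_size, n_groups))
    shifts[affected, :] = rng.normal(0.0, group_effect_log2, (n_affected, n_groups))

    sample_ids, groups, clones, cols = [], [], [], []
    for g in range(n_groups):
        for k in range(n_clones):
            sample_ids.append(f"group{g+1}_c{k+1}")
            groups.append(f"group{g+1}")
            clones.append(f"c{k+1}")
            cols.append(base_log2 + shifts[:, g])
    log2_mat = np.column_stack(cols)
    log2_mat += rng.normal(0.0, c.noise_log_sd, log2_mat.shape)
    return ExpressionCompendium(
        tpm=pd.DataFrame(np.power(2.0, log2_mat), index=gene_ids, columns=sample_ids),
        sample_sheet=pd.DataFrame(
            {"sample_id": sample_ids, "group": groups, "clone": clones}),
    )


# --------------------------------------------------------------------------
# pH / lactate trace simulation


@dataclass
class TraceConfig:
    """Parameters of the simulated lactate-perfusion pH trace.

    The intracellular proton concentration [H] (nM) rests at
    ``10**(9 - resting_ph)`` until lactate onset ``t_on``, rises
    exponentially with amplitude ``influx_amplitude`` and time constant
    ``influx_tau`` while lactate is present, and after washout at ``t_off``
    relaxes with ``recovery_tau`` toward the pre-lactate level plus
    ``post_resting_shift``. Gaussian noise (sd ``noise_sd_ph``) is added in
    pH space, because the instrument reports ratiometric pH.
    """

    resting_ph: float = 7.4
    influx_amplitude: float = 60.0   # nM
    influx_tau: float = 20.0         # s
    recovery_tau: float = 20.0       # s
    post_resting_shift: float = 10.0  # nM
    t_on: float = 60.0               # s
    t_off: float = 180.0             # s
    t_end: float = 330.0             # s
    sampling_hz: float = 1.0
    noise_sd_ph: float = 0.002       # pH units
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.t_on < self.t_off < self.t_end):
            raise ConfigurationError(
                f"event times must satisfy 0 < t_on < t_off < t_end, got "
                f"({self.t_on}, {self.t_off}, {self.t_end})")
        if self.influx_tau <= 0 or self.recovery_tau <= 0:
            raise ConfigurationError("time constants must be > 0")
        if self.sampling_hz <= 0:
            raise ConfigurationError("sampling_hz must be > 0")
        if not (6 < self.resting_ph < 8):
            raise ConfigurationError("resting_ph must lie in (6, 8)")
        if self.noise_sd_ph < 0:
            raise ConfigurationError("noise_sd_ph must be >= 0")


@dataclass
class KineticTrace:
    """A sampled pH time series plus its analytic ground truth.

    ``ground_truth`` holds the noise-free metric values implied by the
    generating model: resting [H], the continuous-time maximum d[H]/dt
    (amplitude/tau at onset), the resting-to-plateau influx excursion, and
    the post-minus-pre resting shift.
    """

    time_s: np.ndarray
    ph: np.ndarray
    config: TraceConfig
    ground_truth: dict[str, float]

    def write_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        pd.DataFrame({"time_s": self.time_s, "ph": self.ph}).to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"ground_truth": self.ground_truth,
                           "config": asdict(self.config)}, fh, indent=2)

    @classmethod
    def read_csv(cls, path: str | Path) -> "KineticTrace":
        df = pd.read_csv(path)
        return cls(time_s=df["time_s"].to_numpy(float), ph=df["ph"].to_numpy(float),
                   config=None, ground_truth={})


def _analytic_h(t: np.ndarray, c: TraceConfig) -> np.ndarray:
    """Noise-free [H](t) in nM for the piecewise-exponential model."""
    h0 = 10.0 ** (9.0 - c.resting_ph)
    h = np.full_like(t, h0, dtype=float)
    on = (t >= c.t_on) & (t < c.t_off)
    h[on] = h0 + c.influx_amplitude * (1.0 - np.exp(-(t[on] - c.t_on) / c.influx_tau))
    h_off = h0 + c.influx_amplitude * (1.0 - math.exp(-(c.t_off - c.t_on) / c.influx_tau))
    h_post = h0 + c.post_resting_shift
    after = t >= c.t_off
    h[after] = h_post + (h_off - h_post) * np.exp(-(t[after] - c.t_off) / c.recovery_tau)
    return h


def simulate_ph_trace(config: TraceConfig) -> KineticTrace:
    """Simulate a BCECF-style pH trace for a lactate perfusion protocol.

    pH(t) = 9 - log10([H](t) in nM); Gaussian noise is added in pH space.
    The returned ground truth records the analytic (continuous, noise-free)
    metric values.
    """
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)
    dt = 1.0 / c.sampling_hz
    t = np.arange(0.0, c.t_end + dt / 2, dt)
    h = _analytic_h(t, c)
    ph = 9.0 - np.log10(h)
    ph = ph + rng.normal(0.0, c.noise_sd_ph, ph.shape)

    h0 = 10.0 ** (9.0 - c.resting_ph)
    lac = c.t_off - c.t_on
    truth = {
        "resting_h_pre": h0,
        "max_dh_dt": c.influx_amplitude / c.influx_tau,
        "delta_h_influx": c.influx_amplitude * (1.0 - math.exp(-lac / c.influx_tau)),
        "delta_h_resting": c.post_resting_shift,
    }
    return KineticTrace(time_s=t, ph=ph, config=c, ground_truth=truth)
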