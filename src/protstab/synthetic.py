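"""Synthetic mutation datasets with a planted, scale-dependent signal.

The generator emulates the shape of a curated thermodynamic-mutation
dataset: two-class imbalanced substitution records with pH and a ddG whose
sign depends on a known function of residue properties.  The latent signal
acts through scale *differences* between mutant and wild-type residue,

    ddG_latent = sum_i w_i * (scale_i(mut) - scale_i(wt))
                 + c * (mean window hydrophobicity - 1/2) + noise,

so recovering the planted scales genuinely requires the mutant-aware
encoding, and the optional window-context term makes neighbourhood context
(w > 1) informative.  The class ratio is set by thresholding the latent
variable at its (1 - positive_fraction) quantile, which pins the
positive/negative counts at the configured imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import Dataset, MutationInstance, from_records
from .encoding import extract_window
from .scales import AMINO_ACIDS, PAD_TOKEN, PAD_VALUE, ScaleRegistry


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror a curated stability-mutation collection: 1,480 records
    at a 464:1016 positive:negative imbalance, pH spanning the usual
    experimental range, and a two-scale planted signal (composition Co and
    codon number No — two weakly intercorrelated scales, so the planted pair
    is identifiable against correlated proxy scales) with mild observation
    noise.
    """

    n_proteins: int = 40
    seq_length: int = 120
    n_instances: int = 1480
    positive_fraction: float = 464 / 1480
    signal_features: tuple[str, ...] = ("Co", "No")
    signal_weights: tuple[float, ...] = (1.0, 1.0)
    noise_sd: float = 0.3
    context_weight: float = 0.0
    context_feature: str = "H"
    context_window: int = 11
    ph_range: tuple[float, float] = (2.0, 10.0)
    seed: int = 1480

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise SyntheticError("positive_fraction must be in (0, 1)")
        if len(self.signal_features) != len(self.signal_weights):
            raise SyntheticError("one weight per signal feature required")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be non-negative")
        if self.n_instances < 2 or self.n_proteins < 1 or self.seq_length < 1:
            raise SyntheticError("degenerate size parameters")
        lo, hi = self.ph_range
        if not (0 <= lo <= hi <= 14):
            raise SyntheticError("ph_range must be within 0..14")


def _mean_window_value(
    registry: ScaleRegistry, code: str, sequence: str, position: int, w: int
) -> float:
    window = extract_window(sequence, position, w)
    vals = [
        PAD_VALUE if r == PAD_TOKEN else registry.value_of(code, r)
        for r in window
    ]
    return float(np.mean(vals))


def generate(cfg: GeneratorConfig, registry: ScaleRegistry) -> Dataset:
    """Draw a labelled dataset; byte-identical for a fixed seed."""
    for code in cfg.signal_features + (cfg.context_feature,):
        if code not in registry:
            raise SyntheticError(f"signal feature {code!r} not registered")
    rng = np.random.default_rng(cfg.seed)
    letters = np.array(list(AMINO_ACIDS))
    proteins = {
        f"synth{p + 1:03d}": "".join(
            rng.choice(letters, size=cfg.seq_length)
        )
        for p in range(cfg.n_proteins)
    }
    pids = list(proteins)

    records: list[dict] = []
    latents = np.empty(cfg.n_instances)
    seen: set[tuple] = set()
    lo, hi = cfg.ph_range
    i = 0
    while i < cfg.n_instances:
        pid = pids[int(rng.integers(len(pids)))]
        seq = proteins[pid]
        pos = int(rng.integers(1, len(seq) + 1))
        wt = seq[pos - 1]
        mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
        ph = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        key = (pid, pos, mut, round(ph, 6))
        if key in seen:
            continue
        seen.add(key)
        latent = 0.0
        for code, w in zip(cfg.signal_features, cfg.signal_weights):
            latent += w * (
                registry.value_of(code, mut) - registry.value_of(code, wt)
            )
        if cfg.context_weight != 0.0:
            latent += cfg.context_weight * (
                _mean_window_value(
                    registry, cfg.context_feature, seq, pos, cfg.context_window
                )
                - 0.5
            )
        latent += float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
        latents[i] = latent
        records.append(
            {"protein_id": pid, "sequence": seq, "position": pos,
             "wt": wt, "mut": mut, "ph": ph}
        )
        i += 1

    # Center ddG so that the top positive_fraction of the latent variable
    # is non-negative; degenerate (constant) latents cannot hit the ratio.
    if np.ptp(latents) == 0:
        raise SyntheticError(
            "latent signal is constant (degenerate weights with zero noise); "
            "requested class ratio is unreachable"
        )
    threshold = float(np.quantile(latents, 1.0 - cfg.positive_fraction))
    ddg = latents - threshold

    instances = [
        MutationInstance(
            protein_id=r["protein_id"],
            sequence=r["sequence"],
            position=r["position"],
            wt_residue=r["wt"],
            mut_residue=r["mut"],
            ph=r["ph"],
            ddg=float(d),
        )
        for r, d in zip(records, ddg)
    ]
    return from_records(instances)


def null_dataset(cfg: GeneratorConfig, registry: ScaleRegistry) -> Dataset:
    """Dataset whose labels are independent of every feature.

    Same record-generation pipeline, but the latent variable is pure noise
    (all signal weights zeroed; unit noise if the configured noise is 0), so
    any cross-validated AUC above chance is overfitting by construction.
    """
    null_cfg = replace(
        cfg,
        signal_weights=tuple(0.0 for _ in cfg.signal_features),
        context_weight=0.0,
        noise_sd=cfg.noise_sd if cfg.noise_sd > 0 else 1.0,
    )
    return generate(null_cfg, registry)
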