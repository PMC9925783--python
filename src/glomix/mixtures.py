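"""Stimulus designs, virtual odor mixtures, and odor-delivery arithmetic.

A stimulus is a three-odor mixture: one target (go or no-go), one
contextual background, and either the fixed background (training) or one
of eleven novel backgrounds (test).  The full design crosses 4 targets x
4 contexts, giving 16 training mixtures and 176 test mixtures (192
combinations in total).  The reduced design keeps 8 of the 16
target-context combinations for training (each context paired with one
go and one no-go target, so no context predicts valence) and tests on
the complementary 8 combinations crossed with the 11 novel backgrounds
(88 mixtures).

Virtual mixture synthesis follows the measurement pipeline: component
patterns are thresholded (sub-threshold activations zeroed), summed per
glomerulus, and passed through the saturating nonlinearity fitted from
two-odor mixture recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .noise import SaturationModel, apply_saturation
from .synthetic import (CONTEXTS, FIXED_BG, GO_TARGETS, NOGO_TARGETS, NOVELS,
                        TARGETS, GlomerularAtlas)

# Reduced-design target/context pairing: each context sees one go and one
# no-go target during training, each target appears twice; the test
# combinations are the complement.
_REDUCED_TRAIN_COMBOS = (
    ("context_1", "target_go_1"), ("context_1", "target_nogo_1"),
    ("context_2", "target_go_2"), ("context_2", "target_nogo_2"),
    ("context_3", "target_go_1"), ("context_3", "target_nogo_2"),
    ("context_4", "target_go_2"), ("context_4", "target_nogo_1"),
)


@dataclass(frozen=True)
class Mixture:
    """One three-odor stimulus with its valence and design tag."""

    target: str
    context: str
    background: str
    valence: str  # "go" | "nogo"
    set_tag: str  # "training" | "test"

    @property
    def components(self) -> tuple:
        return (self.target, self.context, self.background)


@dataclass(frozen=True)
class MixtureDesign:
    """Enumerated training and test mixtures for one design variant."""

    name: str
    training: tuple
    test: tuple

    @property
    def all_mixtures(self) -> tuple:
        return self.training + self.test


def _valence(target: str) -> str:
    return "go" if target in GO_TARGETS else "nogo"


def enumerate_design(which: str = "full") -> MixtureDesign:
    """Enumerate the full (16/176) or reduced (8/88) stimulus design."""
    if which == "full":
        combos = [(c, t) for t in TARGETS for c in CONTEXTS]
        train_combos = combos
        test_combos = combos
    elif which == "reduced":
        train_combos = list(_REDUCED_TRAIN_COMBOS)
        test_combos = [(c, t) for t in TARGETS for c in CONTEXTS
                       if (c, t) not in _REDUCED_TRAIN_COMBOS]
    else:
        raise ValueError("design must be 'full' or 'reduced'")
    training = tuple(Mixture(t, c, FIXED_BG, _valence(t), "training")
                     for c, t in train_combos)
    test = tuple(Mixture(t, c, nb, _valence(t), "test")
                 for c, t in test_combos for nb in NOVELS)
    return MixtureDesign(name=which, training=training, test=test)


def design_table(design: MixtureDesign) -> pd.DataFrame:
    rows = [{"set": m.set_tag, "target": m.target, "context": m.context,
             "background": m.background, "valence": m.valence}
            for m in design.all_mixtures]
    return pd.DataFrame(rows)


def compose_mixture(components, threshold: float | None,
                    saturation: SaturationModel | None) -> np.ndarray:
    """Threshold -> sum -> saturate, per glomerulus.

    ``components`` is an iterable of mean z-score vectors over a shared ROI
    axis.  Activations weaker than ``threshold`` (i.e. z > threshold, since
    activation is negative) are zeroed per component before summation; pass
    None to skip.  ``saturation`` maps the summed response through the
    fitted nonlinearity; None leaves the linear sum.
    """
    comps = [np.asarray(c, dtype=float) for c in components]
    if not comps:
        raise ValueError("at least one component required")
    n = comps[0].shape[0]
    if any(c.shape != (n,) for c in comps):
        raise ValueError("components must share the ROI axis")
    total = np.zeros(n)
    for c in comps:
        if threshold is not None:
            c = np.where(c > threshold, 0.0, c)
        total += c
    if saturation is not None:
        total = apply_saturation(total, saturation)
    return total


def mixture_patterns(atlas: GlomerularAtlas, mixtures, threshold: float | None,
                     saturation: SaturationModel | None) -> np.ndarray:
    """Compose mean patterns (mixtures x ROIs) for a list of mixtures."""
    return np.stack([
        compose_mixture((atlas.pattern(m.target), atlas.pattern(m.context),
                         atlas.pattern(m.background)), threshold, saturation)
        for m in mixtures])


def similarity(p, q) -> float:
    """Normalized dot product (cosine) between two glomerular patterns.

    1 means identical shapes, 0 orthogonal patterns.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("patterns must share the ROI axis")
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("similarity undefined for a zero pattern")
    return float(p @ q / (np_ * nq))


def serial_dilution(stages, final_flow: float, final_total: float) -> float:
    """Overall fraction of saturated vapor after serial air dilution.

    ``stages`` is a sequence of (odor_flow, carrier_flow) pairs; each stage
    contributes odor_flow / (odor_flow + carrier_flow).  The last stage is
    given directly as ``final_flow / final_total`` (the merged output
    stream).  Flows in any consistent unit (e.g. L/min).

    Example: stages (0.5, 3) and (0.5, 1.5) followed by 0.5 of 5.2 L/min
    gives 0.0034, i.e. 0.34% of saturated vapor.
    """
    frac = final_flow / final_total if final_total > 0 else None
    if frac is None:
        raise ValueError("final total flow must be positive")
    for odor, carrier in stages:
        total = odor + carrier
        if total <= 0:
            raise ValueError("stage total flow must be positive")
        frac *= odor / total
    return frac


def nose_velocity(flow_lpm: float, tube_id_inches: float) -> float:
    """Air speed (m/s) at the nose for a volumetric flow through round tubing.

    ``flow_lpm`` in litres per minute, ``tube_id_inches`` the internal
    diameter in inches.  0.7 L/min through 1/8-inch tubing gives 1.47 m/s.
    """
    if tube_id_inches <= 0:
        raise ValueError("tube diameter must be positive")
    if flow_lpm <= 0:
        raise ValueError("flow must be positive")
    q = flow_lpm * 1e-3 / 60.0  # m^3/s
    r = tube_id_inches * 0.0254 / 2.0  # m
    return q / (np.pi * r**2)
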