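"""Activity-dependent degeneration: multiplicative synaptic weakening driven by firing.

Every 2-ms sample, each mass computes ``loss = exp(-d_eff * maxAct)`` from the
peak excitatory spike density of its last 20 samples and multiplies all of its
synapse strengths (excitatory-to-inhibitory, inhibitory-to-excitatory,
thalamic, and its side of every inter-mass connection) by that loss.

Applying the printed degeneration speed ``d = 0.01`` literally at every 2-ms
sample collapses all synapses within a single epoch (``exp(-0.3)**9096`` is
numerically zero), so the default mode rescales the per-sample rate to
``d_eff = d / kappa``.  ``kappa`` is a calibration constant tuned so that the
spectral and firing-rate milestones (theta rise starting around epoch 15,
excitation/inhibition plateau around epoch 100) unfold over the documented
number of epochs; the literal per-sample mode remains available via
``literal=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AddConfig",
    "SynapticState",
    "max_activity",
    "loss_factor",
    "apply_degeneration",
    "ei_balance",
    "degeneration_timecourse",
]

#: default per-sample rescaling divisor for the degeneration speed, calibrated
#: so the firing-rate and spectral milestones span ~100-200 epochs (3 x the
#: 9096 samples of one epoch)
DEFAULT_KAPPA = 27288.0

#: length of the firing-rate window (2-ms samples) used for maxAct
RATE_WINDOW = 20


@dataclass
class AddConfig:
    """Degeneration-rule settings.

    ``d`` is the degeneration speed; the per-sample rate actually applied is
    ``d`` itself in literal mode and ``d / kappa`` otherwise.
    """

    d: float = 0.01
    kappa: float = DEFAULT_KAPPA
    literal: bool = False
    floor: float = 1e-6
    window: int = RATE_WINDOW

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0 <= self.floor < 1:
            raise ValueError("floor must be in [0, 1)")

    @property
    def d_eff(self) -> float:
        """Per-sample degeneration rate."""
        return self.d if self.literal else self.d / self.kappa


@dataclass
class SynapticState:
    """Per-mass multiplicative synapse strengths plus the recent-rate window.

    All multipliers start at 1 and only ever decrease (multiplication by a
    loss in ``(0, 1]``).  ``w_net`` is a mass's side of each of its inter-mass
    connections; an edge's effective strength is the product of the two
    endpoint-side multipliers.
    """

    n_masses: int
    w_ei: np.ndarray = field(default=None)  # scales C1 (E -> I)
    w_ie: np.ndarray = field(default=None)  # scales C2 (I -> E)
    w_th: np.ndarray = field(default=None)  # scales thalamic input
    w_net: np.ndarray = field(default=None)  # scales incident inter-mass coupling
    rate_history: np.ndarray = field(default=None)  # (window, n) ring buffer
    hist_len: int = 0
    hist_pos: int = 0
    window: int = RATE_WINDOW

    def __post_init__(self) -> None:
        n = self.n_masses
        for name in ("w_ei", "w_ie", "w_th", "w_net"):
            if getattr(self, name) is None:
                setattr(self, name, np.ones(n))
        if self.rate_history is None:
            self.rate_history = np.zeros((self.window, n))

    def record_rates(self, e_rates: np.ndarray) -> None:
        """Push one sample of excitatory spike densities into the window."""
        self.rate_history[self.hist_pos] = e_rates
        self.hist_pos = (self.hist_pos + 1) % self.window
        self.hist_len = min(self.hist_len + 1, self.window)

    def max_activity(self) -> np.ndarray:
        """Per-mass maxAct over the recorded window."""
        if self.hist_len == 0:
            raise ValueError("empty rate history")
        return self.rate_history[: self.hist_len].max(axis=0)

    def multipliers(self) -> np.ndarray:
        """(4, n) stack of the strength arrays (E->I, I->E, thalamic, inter-mass)."""
        return np.stack([self.w_ei, self.w_ie, self.w_th, self.w_net])

    def mean_strength(self) -> float:
        return float(self.multipliers().mean())


def max_activity(rate_history: np.ndarray, window: int = RATE_WINDOW) -> float | np.ndarray:
    """Highest excitatory firing rate over the most recent ``window`` samples.

    ``rate_history`` is ordered oldest-first along axis 0; histories longer
    than the window are truncated to the most recent entries (including the
    current sample).
    """
    h = np.asarray(rate_history, dtype=float)
    if h.shape[0] == 0:
        raise ValueError("empty rate history")
    return h[-window:].max(axis=0)


def loss_factor(max_act, d_eff: float):
    """``loss = exp(-d_eff * maxAct)``, in ``(0, 1]``."""
    max_act = np.asarray(max_act, dtype=float)
    if np.any(max_act < 0):
        raise ValueError("maxAct must be >= 0")
    if d_eff < 0:
        raise ValueError("d_eff must be >= 0")
    out = np.exp(-d_eff * max_act)
    return float(out) if out.ndim == 0 else out


def apply_degeneration(
    synapses: SynapticState, loss_per_mass: np.ndarray, floor: float = 0.0
) -> SynapticState:
    """Multiply every synapse multiplier of each mass by that mass's loss (in place)."""
    loss = np.asarray(loss_per_mass, dtype=float)
    if np.any(loss <= 0) or np.any(loss > 1):
        raise ValueError("loss values must be in (0, 1]")
    for w in (synapses.w_ei, synapses.w_ie, synapses.w_th, synapses.w_net):
        np.multiply(w, loss, out=w)
        if floor > 0:
            np.maximum(w, floor, out=w)
    return synapses


def ei_balance(e_rates, i_rates) -> float:
    """Normalized excitation/inhibition balance ``E / (E + I)``.

    Inputs may be scalars or arrays (e.g. per-mass epoch-averaged rates);
    arrays are averaged before the ratio is taken.
    """
    e = float(np.mean(e_rates))
    i = float(np.mean(i_rates))
    if e + i <= 0:
        raise ValueError("E + I must be positive")
    return e / (e + i)


def degeneration_timecourse(records) -> pd.DataFrame:
    """Per-epoch summary table: mean firing rates, E/I balance, mean synapse strength."""
    rows = []
    for rec in records:
        e = float(rec.e_rates.mean())
        i = float(rec.i_rates.mean())
        rows.append(
            {
                "epoch": rec.epoch_index,
                "mean_E": e,
                "mean_I": i,
                "EI_balance": ei_balance(e, i),
                "mean_strength": float(np.mean(rec.synaptic_strengths)),
            }
        )
    if not rows:
        raise ValueError("need at least one epoch")
    return pd.DataFrame(rows)
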