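"""ELBO pieces: Gaussian KL, token reconstruction NLL, beta schedules.

The training objective is ``L = beta * D_KL(q(z|x) || N(0, I)) + NLL``
with a single-sample reparameterized estimate of the reconstruction
term.  ``beta`` is tiny (5e-5 to 1e-4) and time-scheduled — either one
monotonic linear ramp over the training horizon or several equal
cyclical ramps that reset to the low value at each cycle boundary — to
hold off posterior collapse while the decoder learns.

Reduction convention: reconstruction is summed over the non-pad tokens
of a sequence and averaged over molecules; KL is summed over latent
dimensions and averaged over molecules.  A per-token mean would shrink
the reconstruction term by two orders of magnitude and make the printed
beta range meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, log_softmax
from .model import LatentDistribution


def kl_divergence(dist: LatentDistribution) -> Tensor:
    """Closed-form KL of the diagonal Gaussian q(z|x) from N(0, I).

    Per molecule ``sum_d 0.5 * (mu_d^2 + sigma_d^2 - 1 - ln sigma_d^2)``,
    then averaged over the batch.  Always >= 0, and 0 iff mu = 0,
    sigma = 1.
    """
    mu, log_sigma = dist.mu, dist.log_sigma
    if not (np.isfinite(mu.data).all() and np.isfinite(log_sigma.data).all()):
        raise ValueError("non-finite posterior parameters")
    sigma_sq = (log_sigma * 2.0).exp()
    per_mol = ((mu**2.0 + sigma_sq - 1.0 - log_sigma * 2.0) * 0.5).sum(axis=-1)
    return per_mol.mean() if per_mol.ndim else per_mol


def reconstruction_nll(logits: Tensor, targets: np.ndarray, pad_id: int) -> Tensor:
    """Negative log-likelihood of ``targets`` under ``logits``.

    ``logits`` is (B, L, V) aligned so position t predicts ``targets[:, t]``
    (i.e. the caller feeds tokens[:, :-1] to the decoder and passes
    tokens[:, 1:] here).  Summed over non-pad positions, averaged over
    the batch; pad positions contribute exactly zero.
    """
    targets = np.asarray(targets, dtype=np.int64)
    if logits.shape[:2] != targets.shape:
        raise ValueError(f"logits {logits.shape[:2]} misaligned with targets {targets.shape}")
    B, L = targets.shape
    logp = log_softmax(logits, axis=-1)
    bi, li = np.meshgrid(np.arange(B), np.arange(L), indexing="ij")
    # pads are redirected to index 0 then masked out, so they never index
    # out of range and never contribute
    mask = (targets != pad_id).astype(np.float64)
    safe = np.where(targets == pad_id, 0, targets)
    token_logp = logp[(bi, li, safe)] * mask
    return -(token_logp.sum(axis=1).mean())


@dataclass
class BetaSchedule:
    """Policy for the KL weight beta over a training horizon.

    ``monotonic``: one linear ramp from ``beta_low`` at step 0 to
    ``beta_high`` at ``total_steps``.  ``cyclical``: the horizon splits
    into ``n_cycles`` equal cycles, each an independent linear ramp from
    ``beta_low`` to ``beta_high`` that resets at the cycle boundary.
    """

    mode: str = "monotonic"
    beta_low: float = 5e-5
    beta_high: float = 1e-4
    n_cycles: int = 1
    total_steps: int = 100

    def __post_init__(self):
        if self.mode not in ("monotonic", "cyclical"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if not 0 <= self.beta_low <= self.beta_high:
            raise ValueError("need 0 <= beta_low <= beta_high")
        if self.n_cycles < 1 or self.total_steps < 1:
            raise ValueError("n_cycles and total_steps must be >= 1")
        if self.mode == "cyclical" and self.total_steps % self.n_cycles:
            raise ValueError("n_cycles must divide total_steps into equal cycles")


def beta_at(schedule: BetaSchedule, step: int) -> float:
    """Beta value at integer ``step`` in [0, total_steps]."""
    if not 0 <= step <= schedule.total_steps:
        raise ValueError(f"step {step} outside [0, {schedule.total_steps}]")
    lo, hi = schedule.beta_low, schedule.beta_high
    if schedule.mode == "monotonic":
        return lo + (hi - lo) * step / schedule.total_steps
    cycle_len = schedule.total_steps // schedule.n_cycles
    if step == schedule.total_steps:  # clamp the closing endpoint
        return hi
    pos = step % cycle_len
    if cycle_len == 1:
        return lo
    return lo + (hi - lo) * pos / (cycle_len - 1)


@dataclass
class LossBreakdown:
    """The four logged loss fields; ``total = beta * kl + recon``."""

    kl: float
    recon: float
    beta: float
    total: float


def total_loss(kl, recon, beta: float):
    """Combine terms; returns (total, LossBreakdown).

    ``kl``/``recon`` may be Tensors (training path, ``total`` carries
    gradients) or floats.
    """
    total = kl * beta + recon
    kl_v = float(kl.data) if isinstance(kl, Tensor) else float(kl)
    recon_v = float(recon.data) if isinstance(recon, Tensor) else float(recon)
    if not (np.isfinite(kl_v) and np.isfinite(recon_v)):
        raise ValueError("non-finite loss terms")
    breakdown = LossBreakdown(kl=kl_v, recon=recon_v, beta=float(beta),
                              total=beta * kl_v + recon_v)
    return total, breakdown
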