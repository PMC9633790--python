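"""Closed-form RBF transcription dynamics.

Each gene's spliced abundance is modelled as a Gaussian bump over latent
time,

    s_g(t) = h_g * exp(-a_g * (t - tau_g)^2) + o_g,

and the unspliced abundance follows from the splicing ODE
``ds/dt = beta*u - gamma*s`` rearranged for ``u``:

    u_g(t) = (s_g'(t) + gamma_g * s_g(t)) / beta_g + i_g.

RNA velocity is the time derivative of the spliced mean.  The peak time
``tau_g`` classifies a gene's behaviour over the observed window
[0, 1]: a peak before the window means the gene is only ever decaying
(repressed), a peak after the window means it is only rising
(induction), and a peak inside the window gives a rise-then-fall
(transient) profile.

All functions broadcast over genes and cells: parameter fields are
arrays of shape ``(G,)`` and time may be a scalar, a per-cell vector
``(N,)`` shared by all genes, or a per-cell-per-gene matrix ``(N, G)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "GeneParams",
    "LatentTime",
    "spliced_mean",
    "unspliced_mean",
    "velocity",
    "neg_log_likelihood",
    "classify_gene",
    "GENE_CLASSES",
]

GENE_CLASSES = ("repressed", "induction", "transient")


@dataclass
class GeneParams:
    """Per-gene parameter bundle defining one phase portrait.

    Attributes
    ----------
    h
        Expression amplitude of the RBF bump (normalized counts, > 0).
    a
        RBF width/scale parameter (1/time^2, > 0); larger means a
        narrower bump.
    tau
        Peak time (time units).  Unbounded: values outside [0, 1]
        put the peak outside the observed window.
    gamma
        Degradation rate (1/time, > 0).
    beta
        Splicing rate (1/time, > 0).
    b
        Residual precision ``b = 1 / (sqrt(2*pi) * sigma)``
        (1/normalized counts, > 0).
    o
        Spliced offset (normalized counts).
    i
        Unspliced offset (normalized counts).
    """

    h: np.ndarray
    a: np.ndarray
    tau: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    b: np.ndarray = field(default=None)  # type: ignore[assignment]
    o: np.ndarray = field(default=None)  # type: ignore[assignment]
    i: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        g = self.h.shape[0]
        for name in ("a", "tau", "gamma", "beta", "b", "o", "i"):
            v = getattr(self, name)
            if v is None:
                v = np.ones(g) if name == "b" else np.zeros(g)
            v = np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=float)), (g,)).copy()
            setattr(self, name, v)
        for name in ("h", "a", "gamma", "beta", "b"):
            v = getattr(self, name)
            if np.any(v <= 0):
                raise ValueError(f"GeneParams.{name} must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.h.shape[0]

    def subset(self, idx) -> "GeneParams":
        return GeneParams(
            h=self.h[idx], a=self.a[idx], tau=self.tau[idx],
            gamma=self.gamma[idx], beta=self.beta[idx], b=self.b[idx],
            o=self.o[idx], i=self.i[idx],
        )

    def copy(self) -> "GeneParams":
        return replace(
            self, h=self.h.copy(), a=self.a.copy(), tau=self.tau.copy(),
            gamma=self.gamma.copy(), beta=self.beta.copy(), b=self.b.copy(),
            o=self.o.copy(), i=self.i.copy(),
        )


@dataclass
class LatentTime:
    """Per-cell latent time, either shared across genes or gene-specific.

    ``mode='unified'`` holds one scalar per cell (shape ``(N,)``);
    ``mode='independent'`` holds a cell-by-gene matrix (shape ``(N, G)``).
    Values live in the closed interval [0, 1].
    """

    mode: Literal["unified", "independent"]
    t: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.mode == "unified" and self.t.ndim != 1:
            raise ValueError("unified latent time must be 1-D (one value per cell)")
        if self.mode == "independent" and self.t.ndim != 2:
            raise ValueError("independent latent time must be 2-D (cells x genes)")
        if self.t.size and (self.t.min() < -1e-9 or self.t.max() > 1 + 1e-9):
            raise ValueError("latent time must lie in [0, 1]")


def _delta(params: GeneParams, t) -> np.ndarray:
    """Broadcast t against per-gene peak times: result shape (..., G)."""
    t = np.asarray(t, dtype=float)
    if t.ndim <= 1:
        return t[..., None] - params.tau if t.ndim == 1 else t - params.tau
    if t.shape[-1] != params.n_genes:
        raise ValueError(
            f"time matrix has {t.shape[-1]} gene columns, expected {params.n_genes}"
        )
    return t - params.tau


def spliced_mean(params: GeneParams, t) -> np.ndarray:
    """Expected spliced expression ``h*exp(-a*(t-tau)^2) + o``.

    The maximum over ``t`` is ``h + o``, attained at ``t = tau``; the
    value decays to the offset ``o`` in both tails.
    """
    d = _delta(params, t)
    return params.h * np.exp(-params.a * d * d) + params.o


def unspliced_mean(params: GeneParams, t) -> np.ndarray:
    """Expected unspliced expression derived from the splicing ODE.

    ``u(t) = (s'(t) + gamma*s(t)) / beta + i`` where ``s'`` is the time
    derivative of the RBF term (the constant offset ``o`` drops out of
    the derivative but still enters through ``gamma*s``).
    """
    d = _delta(params, t)
    r = np.exp(-params.a * d * d)
    s = params.h * r + params.o
    sp = params.h * r * (-2.0 * params.a * d)
    return (sp + params.gamma * s) / params.beta + params.i


def velocity(params: GeneParams, t, include_offset: bool = False) -> np.ndarray:
    """RNA velocity ``ds/dt`` at the given latent times.

    By default the exact derivative of the spliced mean is returned,
    ``(s(t) - o) * (-2a(t - tau))``, which excludes the constant offset
    from the product.  ``include_offset=True`` multiplies the full
    ``s(t)`` (offset included) by the same factor instead, for
    compatibility with implementations that define velocity that way;
    the two agree whenever ``o = 0``.
    """
    d = _delta(params, t)
    bump = params.h * np.exp(-params.a * d * d)
    if include_offset:
        bump = bump + params.o
    return bump * (-2.0 * params.a * d)


def neg_log_likelihood(params: GeneParams, u_obs, s_obs, t) -> np.ndarray:
    """Per-gene negative log-likelihood of observed (u, s) pairs.

    Residuals in the (u, s) phase plane are modelled as isotropic
    Gaussian with per-gene precision ``b``; up to constants the loss is

        l_g = pi * b^2 * sum_i |x_i_obs - x_hat_i(t)|^2 - log(b).

    Returns an array of shape ``(G,)`` (a 0-d-compatible length-1 array
    for a single gene).  Lower is better; a perfect fit gives
    ``-log(b)``.
    """
    u_obs = np.asarray(u_obs, dtype=float)
    s_obs = np.asarray(s_obs, dtype=float)
    if not (np.isfinite(u_obs).all() and np.isfinite(s_obs).all()):
        raise ValueError("non-finite values in observed unspliced/spliced layers")
    if u_obs.ndim == 1:
        u_obs = u_obs[:, None]
        s_obs = s_obs[:, None]
    e_u = u_obs - unspliced_mean(params, t)
    e_s = s_obs - spliced_mean(params, t)
    sq = (e_u * e_u + e_s * e_s).sum(axis=0)
    return np.pi * params.b**2 * sq - np.log(params.b)


def classify_gene(params: GeneParams) -> np.ndarray:
    """Classify genes by peak time: repressed, induction, or transient.

    ``tau <= 0`` means the expression peak precedes the observed window
    (the gene only decays: repressed); ``tau >= 1`` puts the peak after
    the window (monotone rise: induction); ``0 < tau < 1`` gives a
    rise-and-fall (transient) profile.  Every real ``tau`` maps to
    exactly one label.
    """
    labels = np.full(params.n_genes, "transient", dtype=object)
    labels[params.tau <= 0] = "repressed"
    labels[params.tau >= 1] = "induction"
    return labels.astype(str)
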