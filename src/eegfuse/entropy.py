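"""Permutation entropy, static and time-varying.

Permutation entropy (PE) quantifies the complexity of a time series as
the Shannon entropy of its ordinal-pattern distribution: each window of
``m`` samples spaced ``tau`` apart is reduced to the permutation that
sorts it, and PE = -sum_j P_j log P_j over the relative frequencies P_j
of the observed patterns. PE lies in [0, log m!]; a monotone sequence
gives 0 (one pattern), white noise approaches log m!. Because PE depends
only on rank order, it is exactly invariant under strictly monotone
transforms of the signal.

Ties are broken by order of occurrence (stable sort), so permuting equal
values never changes the assigned pattern; an optional seeded jitter is
available when ties are frequent (e.g. coarsely quantised data).

Time-varying PE evaluates PE in consecutive non-overlapping windows to
monitor complexity drift, e.g. across a clinical state change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from eegfuse.preprocess import BandDefinition, EpochSet, bandpass_array

__all__ = ["PEConfig", "pe_per_band", "permutation_entropy", "time_varying_pe"]

_MAX_ORDER = 10


@dataclass(frozen=True)
class PEConfig:
    """Permutation-entropy parameters.

    Parameters
    ----------
    m
        Ordinal pattern length (embedding dimension), 2..10.
    tau
        Embedding lag in samples, >= 1.
    log_base
        ``"e"`` for nats (default) or ``"2"`` for bits.
    normalize
        Divide by log(m!) so the result lies in [0, 1].
    jitter
        Standard deviation of optional tie-breaking noise relative to
        the signal's scale; 0 disables it.
    jitter_seed
        Seed for the jitter noise.
    """

    m: int = 4
    tau: int = 1
    log_base: str = "e"
    normalize: bool = False
    jitter: float = 0.0
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.m <= _MAX_ORDER:
            raise ValueError(f"pattern length m must be in [2, {_MAX_ORDER}], got {self.m}")
        if self.tau < 1:
            raise ValueError(f"lag tau must be >= 1, got {self.tau}")
        if self.log_base not in ("e", "2"):
            raise ValueError(f"log_base must be 'e' or '2', got {self.log_base!r}")

    @property
    def min_length(self) -> int:
        """Smallest signal length yielding at least two embedded vectors."""
        return (self.m - 1) * self.tau + 2

    def _log(self, x: np.ndarray) -> np.ndarray:
        return np.log2(x) if self.log_base == "2" else np.log(x)

    @property
    def max_entropy(self) -> float:
        h = math.log(math.factorial(self.m))
        return h / math.log(2) if self.log_base == "2" else h


def _pattern_codes(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Integer code of the ordinal pattern of every embedded vector."""
    n = x.size
    n_vec = n - (m - 1) * tau
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    emb = x[idx]
    # stable argsort: ties resolved by position, deterministically
    perm = np.argsort(emb, axis=1, kind="stable")
    return perm @ (m ** np.arange(m))


def permutation_entropy(x: np.ndarray, cfg: PEConfig = PEConfig()) -> float:
    """Permutation entropy of a 1-D signal.

    Only observed patterns contribute (0 log 0 = 0). Raises if the signal
    is too short to embed at least two vectors.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < cfg.min_length:
        raise ValueError(
            f"signal of {x.size} samples too short for m={cfg.m}, tau={cfg.tau} "
            f"(need >= {cfg.min_length})"
        )
    if cfg.jitter > 0:
        rng = np.random.default_rng(cfg.jitter_seed)
        scale = np.std(x)
        scale = scale if scale > 0 else 1.0
        x = x + rng.standard_normal(x.size) * cfg.jitter * scale
    codes = _pattern_codes(x, cfg.m, cfg.tau)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * cfg._log(p)).sum())
    if cfg.normalize:
        h /= cfg.max_entropy
    return h


def time_varying_pe(
    x: np.ndarray,
    cfg: PEConfig = PEConfig(),
    n_windows: int | None = None,
    window_samples: int | None = None,
) -> np.ndarray:
    """PE in consecutive non-overlapping windows of a 1-D signal.

    Give exactly one of ``n_windows`` (equal split, remainder discarded)
    or ``window_samples``. Element ``t`` is the PE of window ``t``; the
    leftover tail shorter than one window is discarded.
    """
    x = np.asarray(x, dtype=float).ravel()
    if (n_windows is None) == (window_samples is None):
        raise ValueError("give exactly one of n_windows or window_samples")
    if n_windows is not None:
        if n_windows < 1:
            raise ValueError(f"n_windows must be >= 1, got {n_windows}")
        window_samples = x.size // n_windows
    if window_samples < cfg.min_length:
        raise ValueError(
            f"window of {window_samples} samples too short for m={cfg.m}, tau={cfg.tau}"
        )
    n_win = x.size // window_samples
    return np.array(
        [
            permutation_entropy(x[t * window_samples : (t + 1) * window_samples], cfg)
            for t in range(n_win)
        ]
    )


def pe_per_band(
    eps: EpochSet,
    bands: list[BandDefinition],
    cfg: PEConfig = PEConfig(),
) -> pd.DataFrame:
    """PE per band x epoch x channel of an epoch set, as a tidy table.

    Each epoch/channel signal is zero-phase band-pass filtered into every
    requested band before PE is computed. Returns a DataFrame with
    columns ``band``, ``epoch``, ``channel``, ``pe``.
    """
    rows = []
    for band in bands:
        filt = bandpass_array(eps.epochs, band, eps.fs)
        for e in range(eps.n_epochs):
            for c in range(eps.n_channels):
                rows.append(
                    {
                        "band": band.name,
                        "epoch": e,
                        "channel": eps.channel_labels[c],
                        "pe": permutation_entropy(filt[e, c], cfg),
                    }
                )
    return pd.DataFrame(rows)
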