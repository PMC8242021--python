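"""Gaussian noise sources for the DP mechanism.

The privacy guarantee of DP-SGD assumes the noise is unpredictable to an
adversary, so the default source draws entropy from the operating system's
CSPRNG (``os.urandom``) and maps uniforms to normals with the Box-Muller
transform.  A seeded, *insecure* source is provided for tests and
reproducibility studies only; it refuses to masquerade as secure and every
draw from it is flagged in the log.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseRequest", "SecureNoiseError", "gaussian", "GaussianNoiseSource"]

logger = logging.getLogger("privgrad.noise")


class SecureNoiseError(ValueError):
    """Misuse of the noise API (e.g. seeding a secure source)."""


@dataclass(frozen=True)
class NoiseRequest:
    """A request for ``length`` i.i.d. N(0, std^2) draws.

    ``std`` is sigma * C in DP-SGD use.  ``seed`` is honoured only when
    ``secure`` is False; supplying one with ``secure=True`` is an error,
    not a silent downgrade.
    """

    length: int
    std: float
    secure: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise SecureNoiseError(f"length must be >= 0, got {self.length}")
        if self.std < 0:
            raise SecureNoiseError(f"std must be >= 0, got {self.std}")
        if self.secure and self.seed is not None:
            raise SecureNoiseError(
                "a seed was supplied with secure=True; seeded noise is not "
                "cryptographically secure — set secure=False explicitly"
            )


def _secure_uniforms(n: int) -> np.ndarray:
    """n uniforms in (0, 1) from os.urandom, via 64-bit integers."""
    raw = np.frombuffer(os.urandom(8 * n), dtype=np.uint64)
    # map {0..2^64-1} -> (0,1): never exactly 0 or 1, safe for log()
    return (raw.astype(np.float64) + 0.5) / 2.0**64


def _box_muller(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    r = np.sqrt(-2.0 * np.log(u1))
    theta = 2.0 * np.pi * u2
    return np.concatenate([r * np.cos(theta), r * np.sin(theta)])


def gaussian(request: NoiseRequest) -> np.ndarray:
    """Draw the requested noise vector.

    Secure mode consumes OS entropy and applies Box-Muller; insecure mode
    applies the same transform to uniforms from a seeded PCG64 stream and
    is therefore bit-reproducible for a fixed seed.
    """
    n = request.length
    if n == 0:
        return np.empty(0, dtype=np.float64)
    if request.std == 0.0:
        return np.zeros(n, dtype=np.float64)
    half = (n + 1) // 2
    if request.secure:
        u = _secure_uniforms(2 * half)
    else:
        logger.warning("drawing INSECURE seeded noise (seed=%s)", request.seed)
        rng = np.random.Generator(np.random.PCG64(request.seed))
        # shift into (0,1) so log() is finite
        u = (rng.random(2 * half) * (1.0 - 2e-16)) + 1e-16
    z = _box_muller(u[:half], u[half:])
    return request.std * z[:n]


class GaussianNoiseSource:
    """A reusable noise source with fixed security mode.

    The DP-SGD engine asks this object for vectors of given length and
    std; the mode (secure vs. seeded-insecure) is fixed at construction
    so that a training loop cannot silently switch to a weak source.
    """

    def __init__(self, secure: bool = True, seed: int | None = None):
        if secure and seed is not None:
            raise SecureNoiseError("secure noise source cannot be seeded")
        self.secure = secure
        self._seed = seed
        self._counter = 0

    def draw(self, length: int, std: float) -> np.ndarray:
        if self.secure:
            return gaussian(NoiseRequest(length, std, secure=True))
        # derive a fresh stream per call so repeated draws differ but the
        # whole sequence is reproducible from the base seed
        seed = None if self._seed is None else (self._seed + self._counter) % (2**31)
        self._counter += 1
        return gaussian(NoiseRequest(length, std, secure=False, seed=seed))

    def uniform(self, length: int) -> np.ndarray:
        """Uniforms in (0,1), used by the Poisson batch sampler."""
        if self.secure:
            return _secure_uniforms(length)
        seed = None if self._seed is None else (self._seed + self._counter) % (2**31)
        self._counter += 1
        rng = np.random.Generator(np.random.PCG64(seed))
        return rng.random(length)
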