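"""Alternating binary series and the normalized complex wavefunction.

For a (0,1) indicator vector x of length N the alternating cumulative
series is

    Phi_k = sum_{j=1..k} (-1)^(j-1) x_j ,

an integer-valued walk whose signed increments recover x through
|Phi_k - Phi_{k-1}| = x_k. Writing lambda_N = Phi_N (the series
endpoint) and N+1 for the number of ones, the mode-n wavefunction is

    psi_n(k) = A (-1)^(k-1) x_k exp(i n pi Phi_k / lambda_N),
    A = 1 / sqrt(N+1),

so that sum_k |psi_n(k)|^2 = 1 for every integer mode n >= 1. Because
x_k in {0,1}, |psi_n(k)|^2 = x_k / N+1 independently of n: modes differ
only in phase. At k = N the phase collapses to n*pi, giving the closed
endpoint form psi_n(N) = (-1)^n (-1)^(N-1) x_N / sqrt(N+1).

Phases are formed from the exact integer Phi in one step (no
incremental complex multiplication), so accumulation error stays at the
level of a single exp evaluation even for genome-length inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WaveSeries",
    "alternating_sum",
    "increments",
    "lambda_n",
    "amplitude",
    "wavefunction",
    "normalization_check",
    "endpoint_form",
    "series_table",
]


def _as_binary(x: np.ndarray | list) -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("binary vector must be non-empty")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("entries must be 0 or 1")
    return x.astype(np.int64)


def alternating_sum(x: np.ndarray | list) -> np.ndarray:
    """Cumulative alternating sum Phi_k = sum_{j<=k} (-1)^(j-1) x_j.

    Signs start at +1 for the first position. The result is integer
    valued throughout.
    """
    x = _as_binary(x)
    signs = np.ones(x.size, dtype=np.int64)
    signs[1::2] = -1
    return np.cumsum(signs * x)


def increments(phi: np.ndarray | list) -> np.ndarray:
    """Recover the (0,1) vector from its alternating cumulative sums.

    Returns |Phi_k - Phi_{k-1}| with Phi_0 = 0; the round trip
    ``increments(alternating_sum(x)) == x`` holds for every valid x.
    An adjacent difference of magnitude > 1 signals a series that no
    (0,1) input can produce.
    """
    phi = np.asarray(phi, dtype=np.int64)
    if phi.size == 0:
        raise ValueError("series must be non-empty")
    d = np.abs(np.diff(phi, prepend=0))
    if (d > 1).any():
        raise ValueError("adjacent difference exceeds 1: not an alternating (0,1) series")
    return d


def lambda_n(x: np.ndarray | list) -> int:
    """Series endpoint Phi_N, the phase scale of the wavefunction."""
    return int(alternating_sum(x)[-1])


def amplitude(n_one: int) -> float:
    """Normalization amplitude A = 1/sqrt(N+1) (positive root).

    A projection with no ones admits no normalized wavefunction.
    """
    if n_one < 1:
        raise ValueError("all-zero projection: wavefunction is unnormalizable (N+1 = 0)")
    return 1.0 / np.sqrt(n_one)


@dataclass(frozen=True)
class WaveSeries:
    """A (0,1) vector with its alternating series and wavefunction.

    ``psi`` carries the raw (A-scaled) complex values; divide by
    ``amplitude`` for the unit-amplitude form sometimes used in plots.
    """

    x: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    signed_terms: np.ndarray = field(repr=False)
    lam: int
    n_one: int
    amplitude: float
    mode: int
    psi: np.ndarray = field(repr=False)

    @property
    def psi_over_amplitude(self) -> np.ndarray:
        return self.psi / self.amplitude


def wavefunction(x: np.ndarray | list, mode: int = 1) -> WaveSeries:
    """Mode-n complex wavefunction of a (0,1) vector.

    psi_n(k) = A (-1)^(k-1) x_k exp(i n pi Phi_k / lambda_N). Requires
    at least one 1 in x (else A is undefined) and lambda_N != 0 (else
    the phase is undefined). Both degenerate inputs raise ValueError.
    """
    if mode < 1 or int(mode) != mode:
        raise ValueError(f"mode must be an integer >= 1, got {mode!r}")
    x = _as_binary(x)
    n_one = int(x.sum())
    a = amplitude(n_one)  # raises on the all-zero projection
    phi = alternating_sum(x)
    lam = int(phi[-1])
    if lam == 0:
        raise ValueError(
            "lambda_N = Phi_N is zero: the wavefunction phase is undefined "
            "for a balanced alternating series"
        )
    k = np.arange(x.size)
    parity = np.where(k % 2 == 0, 1.0, -1.0)
    # phase = pi * r with r = n*Phi/lambda; reduce r modulo 2 before the
    # trig call so integer r gives an exactly real value (sinpi-style)
    r = mode * phi / lam
    half_turns = np.round(r)
    frac = r - half_turns
    turn_sign = np.where(half_turns.astype(np.int64) % 2 == 0, 1.0, -1.0)
    phase = turn_sign * (np.cos(np.pi * frac) + 1j * np.sin(np.pi * frac))
    psi = a * parity * x * phase
    signs = np.ones(x.size, dtype=np.int64)
    signs[1::2] = -1
    return WaveSeries(
        x=x,
        phi=phi,
        signed_terms=signs * x,
        lam=lam,
        n_one=n_one,
        amplitude=a,
        mode=int(mode),
        psi=psi,
    )


def normalization_check(ws: WaveSeries) -> float:
    """Total probability sum_k psi_k conj(psi_k); unity by construction."""
    return float(np.sum(ws.psi * np.conj(ws.psi)).real)


def endpoint_form(x: np.ndarray | list, mode: int = 1) -> complex:
    """Closed form of psi_n at the final position k = N.

    There the phase is exactly n*pi, so Euler's identity collapses the
    exponential to (-1)^n:

        psi_n(N) = (-1)^n (-1)^(N-1) x_N / sqrt(N+1).
    """
    x = _as_binary(x)
    n_one = int(x.sum())
    a = amplitude(n_one)
    if lambda_n(x) == 0:
        raise ValueError("lambda_N is zero: endpoint form undefined")
    n = x.size
    return complex(((-1) ** int(mode)) * ((-1) ** (n - 1)) * int(x[-1]) * a)


def series_table(
    ws: WaveSeries,
    k_min: int | None = None,
    k_max: int | None = None,
) -> pd.DataFrame:
    """Tabulate (k, X, Phi, Re_psi, Im_psi) with 1-based positions.

    ``k_min``/``k_max`` restrict rows to an inclusive 1-based window;
    an empty window yields zero rows.
    """
    k = np.arange(1, ws.x.size + 1)
    df = pd.DataFrame(
        {
            "k": k,
            "X": ws.x,
            "Phi": ws.phi,
            "Re_psi": ws.psi.real,
            "Im_psi": ws.psi.imag,
        }
    )
    if k_min is not None:
        df = df[df["k"] >= k_min]
    if k_max is not None:
        df = df[df["k"] <= k_max]
    return df.reset_index(drop=True)
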