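"""Library-size sweeps and the log-linear uniqueness scaling law.

As a CandyCode library grows, the largest number of strings shared between
any two different codes grows — but only logarithmically in library size.
This module measures that statistic over simulated libraries, fits

    mean max shared strings  =  intercept + slope * log10(library size)

by ordinary least squares, and extrapolates the fit to library sizes far
beyond what can be simulated directly (e.g. the ~1e17 draws at which
version-4 UUID collisions reach 1%).  If the extrapolated maximum stays
below the worst-case true-match level (about 21 strings between photos of
the same pill), codes from that design remain distinguishable at that
scale.

The per-library statistic is computed with a flat token representation:
every string occurrence of every code becomes one token, tokens are grouped
by identical string (with within-code duplicates disambiguated so that
multiset-intersection semantics are preserved), and co-occurring code pairs
are counted vectorially.  This keeps 100 000-code libraries tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import StringSet
from .encoder import DEFAULT_CONFIG, EncoderConfig
from .simulator import SimConfig, simulate_library_raw

__all__ = [
    "SweepResult",
    "ScalingFit",
    "max_shared_in_library",
    "run_sweep",
    "fit_scaling",
    "extrapolate",
]


@dataclass(frozen=True)
class SweepResult:
    """Per-size mean and standard deviation of the library maximum shared count."""

    sizes: tuple[int, ...]
    mean_max_shared: tuple[float, ...]
    sd_max_shared: tuple[float, ...]
    replicates: int
    #: raw per-replicate maxima, shape (len(sizes), replicates)
    samples: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be strictly increasing")
        if not (len(self.sizes) == len(self.mean_max_shared) == len(self.sd_max_shared)):
            raise ValueError("per-size arrays must have equal length")


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares fit of mean max shared strings vs log10(library size)."""

    slope_per_decade: float
    intercept: float
    residuals: tuple[float, ...]


def _tokens_from_library(library) -> tuple[np.ndarray, np.ndarray, int]:
    """Flatten a library into (string tokens, code indices, n_codes).

    Accepts either StringSets or the simulator's raw uint8 string rows.
    Tokens are fixed-width byte strings; a trailing byte is reserved for
    the within-code duplicate index assigned later.
    """
    from ._kernels import STRING_WIDTH

    tok_arrays = []
    code_arrays = []
    for i, entry in enumerate(library):
        if isinstance(entry, StringSet):
            raw = np.zeros((entry.total(), STRING_WIDTH), dtype=np.uint8)
            for j, s in enumerate(entry.as_sorted_list()):
                b = s.encode("ascii")
                if len(b) > STRING_WIDTH - 1:
                    raise ValueError(f"string too long: {s!r}")
                raw[j, : len(b)] = np.frombuffer(b, dtype=np.uint8)
        else:
            raw = entry
        if len(raw):
            tok_arrays.append(raw)
            code_arrays.append(np.full(len(raw), i, dtype=np.int64))
    n = len(library)
    if not tok_arrays:
        return np.zeros((0, STRING_WIDTH), np.uint8), np.zeros(0, np.int64), n
    return np.concatenate(tok_arrays), np.concatenate(code_arrays), n


def _max_run_sorted(a: np.ndarray, chunk: int = 8_000_000) -> int:
    """Length of the longest run of equal values in a sorted 1-D array."""
    best = 0
    carry = 0  # length of run continuing from the previous chunk
    prev_last = None
    for start in range(0, len(a), chunk):
        c = a[start : start + chunk]
        if prev_last is not None and c[0] != prev_last:
            carry = 0
        boundaries = np.flatnonzero(c[1:] != c[:-1])
        if len(boundaries) == 0:
            carry += len(c)
            best = max(best, carry)
        else:
            first_run = boundaries[0] + 1 + carry
            runs = np.diff(boundaries)
            last_run = len(c) - 1 - boundaries[-1]
            best = max(best, first_run, last_run)
            if len(runs):
                best = max(best, int(runs.max()))
            carry = last_run
        prev_last = c[-1]
    return int(best)


def _pair_cooccurrences(tokens: np.ndarray, codes: np.ndarray, n_codes: int) -> np.ndarray:
    """Encoded (i < j) code-pair keys, one per shared string occurrence.

    A pair sharing k strings (multiset intersection) appears exactly k
    times in the result.
    """
    T = len(tokens)
    if T == 0:
        return np.zeros(0, dtype=np.int64)
    flat = tokens.reshape(T, -1).view(f"S{tokens.shape[1]}").ravel()
    order = np.lexsort((codes, flat))
    t_s = flat[order]
    c_s = codes[order]

    # occurrence index within each (string, code) group: matching the r-th
    # copy in one code to the r-th copy in another realizes min(count_a,
    # count_b) semantics with plain exact-token matching.
    new_grp = np.empty(T, dtype=bool)
    new_grp[0] = True
    new_grp[1:] = (t_s[1:] != t_s[:-1]) | (c_s[1:] != c_s[:-1])
    starts = np.flatnonzero(new_grp)
    gidx = np.cumsum(new_grp) - 1
    occ = np.arange(T) - starts[gidx]

    new_tok = np.empty(T, dtype=bool)
    new_tok[0] = True
    new_tok[1:] = t_s[1:] != t_s[:-1]
    tok_id = np.cumsum(new_tok) - 1
    key = tok_id * 256 + np.minimum(occ, 255)

    order2 = np.argsort(key, kind="stable")
    key2 = key[order2]
    c2 = c_s[order2]

    grp_start = np.empty(T, dtype=bool)
    grp_start[0] = True
    grp_start[1:] = key2[1:] != key2[:-1]
    offsets = np.flatnonzero(grp_start)
    counts = np.diff(np.append(offsets, T))

    pair_chunks = []
    for g in np.unique(counts[counts >= 2]):
        sel = offsets[counts == g]
        ii, jj = np.triu_indices(g, k=1)
        n_per_row = len(ii)
        rows_per_batch = max(1, 16_000_000 // n_per_row)
        for b in range(0, len(sel), rows_per_batch):
            batch = sel[b : b + rows_per_batch]
            members = c2[batch[:, None] + np.arange(g)]  # (k, g), ascending rows
            pairs = members[:, ii] * np.int64(n_codes) + members[:, jj]
            pair_chunks.append(pairs.ravel())
    if not pair_chunks:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(pair_chunks)


def max_shared_in_library(library: Sequence) -> int:
    """Largest shared-string count between any two distinct codes.

    ``library`` is a sequence of StringSets (or the simulator's raw string
    rows).  Libraries with fewer than 2 codes score 0.
    """
    if len(library) < 2:
        return 0
    tokens, codes, n = _tokens_from_library(library)
    pairs = _pair_cooccurrences(tokens, codes, n)
    if len(pairs) == 0:
        return 0
    pairs.sort()
    return _max_run_sorted(pairs)


def run_sweep(
    sizes: Sequence[int],
    config: SimConfig,
    replicates: int = 20,
    encoder_config: EncoderConfig = DEFAULT_CONFIG,
) -> SweepResult:
    """Mean/sd of the library max shared count at each library size.

    Every (size, replicate) cell simulates a fresh library whose seed is
    derived from ``config.seed``, the size and the replicate index, so the
    sweep is reproducible and cells are independent.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    means, sds, samples = [], [], []
    for si, size in enumerate(sizes):
        maxima = []
        for rep in range(replicates):
            lib_seed = int(
                np.random.SeedSequence((config.seed, si, rep)).generate_state(1)[0]
            )
            lib = simulate_library_raw(
                size, replace(config, seed=lib_seed), encoder_config
            )
            maxima.append(max_shared_in_library(lib))
        arr = np.asarray(maxima, dtype=float)
        means.append(float(arr.mean()))
        sds.append(float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
        samples.append(tuple(int(v) for v in maxima))
    return SweepResult(
        tuple(sizes), tuple(means), tuple(sds), replicates, tuple(samples)
    )


def fit_scaling(result: SweepResult) -> ScalingFit:
    """OLS fit of mean max shared strings against log10(library size).

    Sizes with fewer than 2 codes are excluded (a single code has no pairs,
    so its "maximum shared" of 0 is a definition, not an observation).
    """
    usable = [
        (s, m) for s, m in zip(result.sizes, result.mean_max_shared) if s >= 2
    ]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable sizes to fit")
    x = np.log10([s for s, _ in usable])
    y = np.array([m for _, m in usable])
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (intercept + slope * x)
    return ScalingFit(float(slope), float(intercept), tuple(float(r) for r in residuals))


def extrapolate(fit: ScalingFit, target_size: float) -> float:
    """Predicted max shared strings at ``target_size`` from the fitted law."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    return fit.intercept + fit.slope_per_decade * math.log10(target_size)
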