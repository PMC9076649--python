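"""Monte-Carlo generation of synthetic CandyCodes.

Models a pill face as a disk of radius ``pill_radius`` onto which
``n_particles`` non-overlapping circular particles are placed by random
sequential adsorption (RSA): uniform position proposals, rejected on
overlap, up to ``max_attempts`` proposals per particle.  Colors are drawn
independently from the alphabet's probabilities.  The default of 94
particles matches the median particle count of the 120-pill chocolate test
library that the simulation is calibrated against.

The default particle radius targets an area fraction of 0.45 on the unit
pill — dense enough to look like a real sprinkle-coated pill, comfortably
below the ~0.547 RSA jamming limit so packing essentially always succeeds.

``perturb_candycode`` emulates re-photographing (and physical abuse of) a
pill: small Gaussian jitter of particle positions, optional color misreads
and particle loss.  Jitter changes the near-degenerate angles that decide
Delaunay edge flips, so a perturbed copy retains only part of its original
string set, just as two photographs of the same pill do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from . import _kernels
from .core import ALPHABETS, CandyCode, CandyCodeError, ColorAlphabet, Particle, StringSet
from .encoder import DEFAULT_CONFIG, EncoderConfig, encode_candycode, encode_points_raw

__all__ = [
    "SimConfig",
    "PerturbConfig",
    "PackingError",
    "simulate_candycode",
    "library_member",
    "perturb_candycode",
    "simulate_library",
    "simulate_library_raw",
]

#: Target particle area fraction on the pill face for the default radius.
DEFAULT_AREA_FRACTION = 0.45

#: Reject configurations denser than this (RSA jamming is ~0.547).
MAX_AREA_FRACTION = 0.55


class PackingError(CandyCodeError):
    """Random sequential adsorption failed to place all particles."""


def default_particle_radius(n_particles: int, pill_radius: float = 1.0) -> float:
    """Radius giving area fraction DEFAULT_AREA_FRACTION for n particles."""
    return math.sqrt(DEFAULT_AREA_FRACTION / n_particles) * pill_radius


@dataclass(frozen=True)
class SimConfig:
    """Geometry, alphabet and seeding for synthetic CandyCode generation."""

    n_particles: int = 94
    alphabet: ColorAlphabet = ALPHABETS["A"]
    pill_radius: float = 1.0
    particle_radius: float | None = None
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        r = self.resolved_particle_radius()
        if r >= self.pill_radius:
            raise ValueError("particle_radius must be smaller than pill_radius")
        phi = self.n_particles * r * r / (self.pill_radius**2)
        if phi > MAX_AREA_FRACTION:
            raise ValueError(
                f"area fraction {phi:.3f} exceeds {MAX_AREA_FRACTION} "
                "(above random-packing feasibility)"
            )

    def resolved_particle_radius(self) -> float:
        if self.particle_radius is not None:
            return self.particle_radius
        return default_particle_radius(self.n_particles, self.pill_radius)

    def letters_ascii(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.alphabet.letters).encode("ascii"), dtype=np.uint8
        )

    def cum_probs(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.alphabet.probabilities, dtype=np.float64))


@dataclass(frozen=True)
class PerturbConfig:
    """Noise model for a re-photographed (or abused) CandyCode.

    jitter_sigma
        Standard deviation of the independent Gaussian displacement of each
        particle, in the same units as the coordinates.  ``None`` resolves
        to 0.25 x the default particle radius for the code's particle count
        on a unit pill — calibrated so that a perturbed copy retains
        roughly half of its strings, bracketing the 40-61% retention
        observed between photographs of real pills.
    color_error_rate
        Probability that a particle's color is misread as a uniformly
        random *other* letter.
    """

    jitter_sigma: float | None = None
    color_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_sigma is not None and self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not 0.0 <= self.color_error_rate <= 1.0:
            raise ValueError("color_error_rate must be in [0, 1]")

    def resolved_sigma(self, n_particles: int) -> float:
        if self.jitter_sigma is not None:
            return self.jitter_sigma
        return 0.25 * default_particle_radius(max(n_particles, 1))


def _seed_pair(entropy) -> tuple[int, int]:
    s = np.random.SeedSequence(entropy).generate_state(2)
    return int(s[0]), int(s[1])


#: RSA restarts before declaring a configuration infeasible.  Near the
#: default area fraction a packing occasionally jams (the excluded area of
#: the placed particles can block the last one); restarting with a fresh
#: substream is the standard remedy and keeps codes i.i.d.
_PACKING_RESTARTS = 50


def _simulate_arrays(
    config: SimConfig, pos_seed: int, col_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and ASCII color codes for one simulated code."""
    r = config.resolved_particle_radius()
    placed = -1
    for restart in range(_PACKING_RESTARTS):
        seed = (
            pos_seed
            if restart == 0
            else int(np.random.SeedSequence((pos_seed, restart)).generate_state(1)[0])
        )
        pts, placed = _kernels.rsa_pack(
            config.n_particles, config.pill_radius, r, config.max_attempts, seed
        )
        if placed == config.n_particles:
            break
    if placed < config.n_particles:
        raise PackingError(
            f"placed only {placed} of {config.n_particles} particles after "
            f"{config.max_attempts} attempts each "
            f"({_PACKING_RESTARTS} restarts); density too high"
        )
    idx = _kernels.sample_colors(config.n_particles, config.cum_probs(), col_seed)
    return pts, config.letters_ascii()[idx]


def _arrays_to_code(
    code_id: str, pts: np.ndarray, colors: np.ndarray, alphabet: ColorAlphabet
) -> CandyCode:
    particles = [
        Particle(float(x), float(y), chr(c))
        for (x, y), c in zip(pts, colors)
    ]
    return CandyCode(code_id, particles, alphabet)


def simulate_candycode(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    code_id: str = "sim_000001",
) -> CandyCode:
    """Generate one synthetic CandyCode.

    All randomness derives from ``rng`` if given, else from ``config.seed``.
    Raises PackingError if RSA cannot place every particle.
    """
    if rng is None:
        pos_seed, col_seed = _seed_pair((config.seed, 0))
    else:
        pos_seed = int(rng.integers(0, 2**31))
        col_seed = int(rng.integers(0, 2**31))
    pts, colors = _simulate_arrays(config, pos_seed, col_seed)
    return _arrays_to_code(code_id, pts, colors, config.alphabet)


def library_member(config: SimConfig, index: int) -> CandyCode:
    """Re-materialize library member ``index`` (0-based) as a CandyCode.

    Uses the same per-code substream as :func:`simulate_library`, so the
    returned code encodes to exactly the library entry ``sim_{index+1}``.
    """
    if index < 0:
        raise ValueError("index must be >= 0")
    pos_seed, col_seed = _seed_pair((config.seed, index))
    pts, colors = _simulate_arrays(config, pos_seed, col_seed)
    return _arrays_to_code(f"sim_{index + 1:06d}", pts, colors, config.alphabet)


def perturb_candycode(
    code: CandyCode,
    config: PerturbConfig = PerturbConfig(),
    rng: np.random.Generator | None = None,
    drop_fraction: float = 0.0,
) -> CandyCode:
    """Noisy copy of a code, emulating a second photograph of the same pill.

    Each particle is displaced by independent zero-mean Gaussian noise;
    each color is independently replaced by a uniform random other letter
    with probability ``color_error_rate``; a ``drop_fraction`` of particles
    (rounded down) is removed uniformly at random.
    """
    if not 0.0 <= drop_fraction <= 1.0:
        raise ValueError("drop_fraction must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = len(code.particles)
    sigma = config.resolved_sigma(n)
    xy = code.coordinates() + rng.normal(0.0, sigma, size=(n, 2))
    colors = list(code.colors())
    if config.color_error_rate > 0:
        flips = rng.random(n) < config.color_error_rate
        for i in np.flatnonzero(flips):
            others = [c for c in code.alphabet.letters if c != colors[i]]
            colors[i] = others[rng.integers(len(others))]
    keep = np.arange(n)
    n_drop = int(drop_fraction * n)
    if n_drop:
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))
    particles = [
        Particle(float(xy[i, 0]), float(xy[i, 1]), colors[i]) for i in keep
    ]
    return CandyCode(code.id, particles, code.alphabet)


def simulate_library(
    size: int,
    config: SimConfig,
    encoder_config: EncoderConfig = DEFAULT_CONFIG,
) -> list[StringSet]:
    """Simulate and encode ``size`` independent CandyCodes.

    Codes get ids ``sim_000001``...; each code uses its own random
    substream derived from ``(config.seed, code index)``, so libraries are
    reproducible and per-code results do not depend on generation order.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    out = []
    for i in range(size):
        pos_seed, col_seed = _seed_pair((config.seed, i))
        pts, colors = _simulate_arrays(config, pos_seed, col_seed)
        code = _arrays_to_code(f"sim_{i + 1:06d}", pts, colors, config.alphabet)
        out.append(encode_candycode(code, encoder_config))
    return out


def simulate_library_raw(
    size: int,
    config: SimConfig,
    encoder_config: EncoderConfig = DEFAULT_CONFIG,
) -> list[np.ndarray]:
    """Bulk variant of :func:`simulate_library` for library-scale statistics.

    Returns, per code, the encoder's zero-padded uint8 ASCII string rows
    (see ``encoder.encode_points_raw``); string content and seeding are
    identical to :func:`simulate_library`.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    out = []
    for i in range(size):
        pos_seed, col_seed = _seed_pair((config.seed, i))
        pts, colors = _simulate_arrays(config, pos_seed, col_seed)
        out.append(encode_points_raw(pts, colors, encoder_config))
    return out
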