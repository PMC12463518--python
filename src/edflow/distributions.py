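"""Service-time distribution notation: parsing, moments, seeded sampling.

Scenario files write service times as strings such as ``TRI(2, 3, 5)``,
``1 + 2 * Gamma(0.1, 2.5, 2.5)`` or ``LogNORM(1.3, 2, 1)``.  A spec is
an affine transform ``scale * X + shift`` of a base family variate X.
Three-parameter gamma and lognormal follow the (shape, scale, min) /
(log-mean, log-sd, min) convention: the trailing parameter is a location
minimum added to the base variate before the outer affine transform.
"""

from __future__ import annotations

import math
import re
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "DistributionSpec",
    "RandomStream",
    "DistributionParseError",
    "DistributionDomainError",
    "DistributionWarning",
    "parse_distribution",
    "format_distribution",
    "sample",
    "moments",
]


class DistributionParseError(ValueError):
    """Malformed distribution string."""


class DistributionDomainError(ValueError):
    """Parameters outside the family's domain (e.g. gamma shape <= 0)."""


class DistributionWarning(UserWarning):
    """Recoverable oddity in a printed spec (e.g. ill-ordered triangular)."""


_FAMILIES = {
    "tri": "triangular",
    "tria": "triangular",
    "triangular": "triangular",
    "gamma": "gamma",
    "logn": "lognormal",
    "lognorm": "lognormal",
    "lognormal": "lognormal",
    "exp": "exponential",
    "expo": "exponential",
    "exponential": "exponential",
    "const": "constant",
    "constant": "constant",
}

_CANONICAL_NAME = {
    "triangular": "TRIA",
    "gamma": "GAMMA",
    "lognormal": "LOGNORMAL",
    "exponential": "EXPO",
    "constant": "CONST",
}

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_SPEC_RE = re.compile(
    rf"^\s*(?:(?P<pre>{_NUM})\s*\+\s*)?"
    rf"(?:(?P<scale>{_NUM})\s*\*\s*)?"
    rf"(?P<family>[A-Za-z_]+)\s*\(\s*(?P<args>[^)]*)\)\s*"
    rf"(?:\+\s*(?P<post>{_NUM})\s*)?$"
)


@dataclass(frozen=True)
class DistributionSpec:
    """Canonical parsed service-time law ``scale * X + shift`` (minutes).

    Parameters
    ----------
    family : str
        One of ``triangular``, ``gamma``, ``lognormal``, ``exponential``,
        ``constant``.
    params : tuple of float
        Family-specific parameters:
        triangular ``(min, mode, max)``; gamma ``(shape, scale, min)``;
        lognormal ``(mu, sigma, min)``; exponential ``(mean, min)``;
        constant ``(value,)``.
    scale, shift : float
        Outer affine transform applied to the base variate.
    """

    family: str
    params: Tuple[float, ...]
    scale: float = 1.0
    shift: float = 0.0

    def __post_init__(self):
        if self.family not in _CANONICAL_NAME:
            raise DistributionDomainError(f"unknown family {self.family!r}")
        _validate(self.family, self.params)

    def mean(self) -> float:
        return moments(self)[0]

    def variance(self) -> float:
        return moments(self)[1]


def _validate(family: str, params: Tuple[float, ...]) -> None:
    n = len(params)
    if family == "triangular":
        if n != 3:
            raise DistributionDomainError("triangular needs 3 parameters")
        a, m, b = params
        if not a <= m <= b:
            raise DistributionDomainError(
                f"triangular parameters not ordered: {params}"
            )
    elif family == "gamma":
        if n != 3:
            raise DistributionDomainError("gamma needs canonical 3 parameters")
        shape, scl, _ = params
        if shape <= 0 or scl <= 0:
            raise DistributionDomainError(
                f"gamma shape/scale must be positive, got {params}"
            )
    elif family == "lognormal":
        if n != 3:
            raise DistributionDomainError("lognormal needs canonical 3 parameters")
        if params[1] <= 0:
            raise DistributionDomainError(f"lognormal sigma must be > 0, got {params}")
    elif family == "exponential":
        if n != 2:
            raise DistributionDomainError("exponential needs canonical 2 parameters")
        if params[0] <= 0:
            raise DistributionDomainError(f"exponential mean must be > 0, got {params}")
    elif family == "constant":
        if n != 1:
            raise DistributionDomainError("constant needs 1 parameter")


def parse_distribution(text: str) -> DistributionSpec:
    """Parse a service-time string into a canonical :class:`DistributionSpec`.

    Grammar (case/whitespace-insensitive, ``∗`` accepted for ``*``)::

        [b +] [a *] FAMILY(p1, p2[, p3]) [+ b]

    Ill-ordered triangular parameters are sorted into (min, mode, max)
    with a :class:`DistributionWarning`; a degenerate triangular with
    min == mode == max collapses to a constant.
    """
    if not isinstance(text, str):
        raise DistributionParseError(f"expected string, got {type(text).__name__}")
    normalized = text.replace("∗", "*").replace("−", "-")
    match = _SPEC_RE.match(normalized)
    if match is None:
        raise DistributionParseError(f"cannot parse distribution string {text!r}")
    family_token = match.group("family")
    family = _FAMILIES.get(family_token.lower())
    if family is None:
        raise DistributionParseError(f"unknown family token {family_token!r} in {text!r}")

    raw_args = [tok.strip() for tok in match.group("args").split(",") if tok.strip()]
    params = []
    for tok in raw_args:
        try:
            params.append(float(tok))
        except ValueError:
            raise DistributionParseError(
                f"bad numeric token {tok!r} in {text!r}"
            ) from None

    scale = float(match.group("scale")) if match.group("scale") else 1.0
    shift = 0.0
    if match.group("pre"):
        shift += float(match.group("pre"))
    if match.group("post"):
        shift += float(match.group("post"))

    family, params = _canonicalize(family, params, text)
    return DistributionSpec(family=family, params=tuple(params), scale=scale, shift=shift)


def _canonicalize(family: str, params: list, text: str):
    n = len(params)
    if family == "triangular":
        if n != 3:
            raise DistributionParseError(f"triangular takes 3 parameters, got {n} in {text!r}")
        a, m, b = params
        if not a <= m <= b:
            params = sorted(params)
            warnings.warn(
                f"ill-ordered triangular parameters in {text!r}; "
                f"sorted to (min, mode, max) = {tuple(params)}",
                DistributionWarning,
                stacklevel=3,
            )
        if params[0] == params[2]:
            return "constant", [params[0]]
        return family, params
    if family == "gamma":
        if n == 2:
            params = params + [0.0]
        elif n != 3:
            raise DistributionParseError(f"gamma takes 2 or 3 parameters, got {n} in {text!r}")
        return family, params
    if family == "lognormal":
        if n == 2:
            params = params + [0.0]
        elif n != 3:
            raise DistributionParseError(f"lognormal takes 2 or 3 parameters, got {n} in {text!r}")
        return family, params
    if family == "exponential":
        if n == 1:
            params = params + [0.0]
        elif n != 2:
            raise DistributionParseError(f"exponential takes 1 or 2 parameters, got {n} in {text!r}")
        return family, params
    if family == "constant":
        if n != 1:
            raise DistributionParseError(f"constant takes 1 parameter, got {n} in {text!r}")
        return family, params
    raise DistributionParseError(f"unknown family in {text!r}")  # pragma: no cover


def format_distribution(spec: DistributionSpec) -> str:
    """Render a spec back to the string grammar (parse∘format is identity)."""
    args = ", ".join(f"{p:g}" for p in spec.params)
    out = f"{_CANONICAL_NAME[spec.family]}({args})"
    if spec.scale != 1.0:
        out = f"{spec.scale:g} * {out}"
    if spec.shift != 0.0:
        out = f"{spec.shift:g} + {out}"
    return out


@dataclass
class RandomStream:
    """A named, independently seeded random substream.

    Identical ``(seed, stream_id)`` reproduce identical variate
    sequences; distinct ids give statistically independent PCG64
    streams (seeded via ``SeedSequence([seed, crc32(stream_id)])``).
    ``truncated`` counts variates clipped at zero after the affine
    transform.
    """

    seed: int
    stream_id: str = "main"
    truncated: int = field(default=0, compare=False)

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        self._rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(self.stream_id.encode())])
        )

    @property
    def rng(self) -> np.random.Generator:
        return self._rng

    def copy(self) -> "RandomStream":
        """A fresh stream at the start of the same sequence."""
        return RandomStream(self.seed, self.stream_id)

    def draw(self, spec: DistributionSpec, size: Optional[int] = None):
        return sample(spec, self, size=size)


def _base_draw(spec: DistributionSpec, rng: np.random.Generator, size):
    fam, p = spec.family, spec.params
    if fam == "constant":
        return p[0] if size is None else np.full(size, p[0])
    if fam == "triangular":
        a, m, b = p
        return rng.triangular(a, m, b, size=size)
    if fam == "gamma":
        return rng.gamma(p[0], p[1], size=size) + p[2]
    if fam == "lognormal":
        return rng.lognormal(p[0], p[1], size=size) + p[2]
    if fam == "exponential":
        return rng.exponential(p[0], size=size) + p[1]
    raise DistributionDomainError(fam)  # pragma: no cover


def sample(
    spec: DistributionSpec, stream: RandomStream, size: Optional[int] = None
) -> Union[float, np.ndarray]:
    """Draw variate(s) ``scale * X + shift``, truncated below at zero.

    Truncations are tallied on ``stream.truncated`` (durations cannot
    be negative; the printed laws occasionally allow it through the
    affine transform).
    """
    raw = _base_draw(spec, stream.rng, size)
    value = spec.scale * raw + spec.shift
    if size is None:
        if value < 0:
            stream.truncated += 1
            return 0.0
        return float(value)
    negatives = value < 0
    count = int(np.count_nonzero(negatives))
    if count:
        stream.truncated += count
        value = np.where(negatives, 0.0, value)
    return value


def moments(spec: DistributionSpec) -> Tuple[float, float]:
    """Closed-form (mean, variance) of ``scale * X + shift`` in minutes.

    Ignores the zero-truncation applied by :func:`sample`, which is a
    negligible-mass correction for all the stock service laws.
    """
    fam, p = spec.family, spec.params
    if fam == "constant":
        m, v = p[0], 0.0
    elif fam == "triangular":
        a, mo, b = p
        m = (a + mo + b) / 3.0
        v = (a * a + mo * mo + b * b - a * mo - a * b - mo * b) / 18.0
    elif fam == "gamma":
        shape, scl, minimum = p
        m = shape * scl + minimum
        v = shape * scl * scl
    elif fam == "lognormal":
        mu, sigma, minimum = p
        m = math.exp(mu + sigma * sigma / 2.0) + minimum
        v = (math.exp(sigma * sigma) - 1.0) * math.exp(2.0 * mu + sigma * sigma)
    elif fam == "exponential":
        mean, minimum = p
        m = mean + minimum
        v = mean * mean
    else:  # pragma: no cover
        raise DistributionDomainError(f"no closed-form moments for {fam!r}")
    return spec.scale * m + spec.shift, spec.scale * spec.scale * v
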