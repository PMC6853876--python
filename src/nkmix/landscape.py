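"""NK fitness landscapes: generation, scoring, exhaustive enumeration, text I/O.

An NK landscape assigns a score to every binary string of length ``N``
(``n_loci``).  Locus ``i`` contributes a payoff drawn from a table of
``2**(K+1)`` uniform values, indexed by the joint configuration of locus ``i``
and ``K`` epistatic partner loci (``k_epistasis``); the raw score of a solution
is the mean contribution over all loci.  Higher ``K`` couples more loci
together and makes the landscape more rugged (more local optima).

Scores are reported on a normalized scale

    normalized = (raw / raw_global_max) ** exponent

so the global optimum scores exactly 1 and, with the default exponent of 10,
a typical random solution scores close to 0.

Solutions are handled in two interchangeable encodings:

* a bit array of length ``N`` (0/1 values, locus 0 first), and
* an integer index in ``[0, 2**N)`` where bit ``i`` of the integer
  (LSB = locus 0) holds the value of locus ``i``.

Payoff-table indexing convention (fixed; relied on by the serialization
format and pinned by tests): the focal locus contributes the *most
significant* index bit, followed by the partner loci in stored order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

try:  # numba accelerates the 2**N bulk enumeration; numpy path is equivalent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_EXPONENT = 10.0
#: largest N for which exhaustive 2**N enumeration is attempted
DEFAULT_ENUMERATION_CAP = 24

_FORMAT_MAGIC = "nkmix-landscape-v1"


class ParameterError(ValueError):
    """Invalid landscape parameters or malformed solution input."""


class CapacityError(RuntimeError):
    """The requested exhaustive enumeration exceeds the configured cap."""


class LandscapeFormatError(ValueError):
    """A landscape file could not be parsed."""


# ---------------------------------------------------------------------------
# solution encodings


def bits_to_index(bits) -> int:
    """Pack a 0/1 sequence (locus 0 first) into its integer encoding (LSB = locus 0)."""
    bits = np.asarray(bits, dtype=np.uint64)
    return int((bits << np.arange(bits.size, dtype=np.uint64)).sum())


def index_to_bits(index: int, n_loci: int) -> np.ndarray:
    """Unpack an integer encoding into a length-``n_loci`` uint8 bit array."""
    return ((int(index) >> np.arange(n_loci)) & 1).astype(np.uint8)


def bits_to_string(bits) -> str:
    """Render bits as text with locus 1 (0-indexed locus 0) leftmost."""
    return "".join("1" if b else "0" for b in np.asarray(bits))


def string_to_bits(s: str) -> np.ndarray:
    if set(s) - {"0", "1"}:
        raise ParameterError(f"bit string contains non-binary characters: {s!r}")
    return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


# ---------------------------------------------------------------------------
# bulk enumeration kernels

if _HAVE_NUMBA:

    @njit(cache=False)
    def _raw_table_numba(n, k, partners, tables):  # pragma: no cover - jitted
        size = 1 << n
        out = np.empty(size, np.float64)
        for s in range(size):
            acc = 0.0
            for i in range(n):
                idx = ((s >> i) & 1) << k
                for j in range(k):
                    idx |= ((s >> partners[i, j]) & 1) << (k - 1 - j)
                acc += tables[i, idx]
            out[s] = acc / n
        return out


def _raw_table_numpy(n: int, k: int, partners: np.ndarray, tables: np.ndarray) -> np.ndarray:
    size = 1 << n
    codes = np.arange(size, dtype=np.uint32)
    total = np.zeros(size, dtype=np.float64)
    for i in range(n):
        idx = (((codes >> np.uint32(i)) & np.uint32(1)) << np.uint32(k)).astype(np.uint32)
        for j in range(k):
            p = int(partners[i, j])
            idx |= ((codes >> np.uint32(p)) & np.uint32(1)) << np.uint32(k - 1 - j)
        total += tables[i, idx]
    return total / n


# ---------------------------------------------------------------------------


@dataclass
class NKLandscape:
    """An NK epistatic payoff structure over length-``n_loci`` bit strings.

    ``partners[i]`` lists the ``k_epistasis`` loci (ordered, distinct, != i)
    whose values condition locus ``i``'s payoff; ``payoff_tables[i]`` holds
    the ``2**(k_epistasis+1)`` uniform payoffs for locus ``i``.
    """

    n_loci: int
    k_epistasis: int
    partners: np.ndarray  # (N, K) int64
    payoff_tables: np.ndarray  # (N, 2**(K+1)) float64
    exponent: float = DEFAULT_EXPONENT
    seed: int | None = None
    raw_global_max: float | None = None
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP
    _raw_table: np.ndarray | None = field(default=None, repr=False, compare=False)
    _norm_table: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n, k = self.n_loci, self.k_epistasis
        if n < 1:
            raise ParameterError("n_loci must be >= 1")
        if not 0 <= k <= n - 1:
            raise ParameterError("k_epistasis must satisfy 0 <= K <= N-1")
        self.partners = np.asarray(self.partners, dtype=np.int64).reshape(n, k)
        self.payoff_tables = np.asarray(self.payoff_tables, dtype=np.float64).reshape(
            n, 1 << (k + 1)
        )
        for i in range(n):
            row = self.partners[i]
            if len(set(row.tolist())) != k or (i in row) or row.size and (
                row.min() < 0 or row.max() >= n
            ):
                raise ParameterError(f"invalid partner set for locus {i}: {row}")

    # -- per-solution scoring -------------------------------------------------

    @property
    def table_size(self) -> int:
        return 1 << (self.k_epistasis + 1)

    def _check_solution(self, solution) -> np.ndarray:
        bits = np.asarray(solution, dtype=np.uint8)
        if bits.shape != (self.n_loci,):
            raise ParameterError(
                f"solution length {bits.size} != n_loci {self.n_loci}"
            )
        return bits

    def component_index(self, solution, locus: int) -> int:
        """Payoff-table index for ``locus``: focal bit most significant, then partners."""
        bits = self._check_solution(solution)
        if not 0 <= locus < self.n_loci:
            raise ParameterError(f"locus {locus} out of range")
        idx = int(bits[locus]) << self.k_epistasis
        for j, p in enumerate(self.partners[locus]):
            idx |= int(bits[p]) << (self.k_epistasis - 1 - j)
        return idx

    def component_score(self, solution, locus: int) -> float:
        return float(self.payoff_tables[locus, self.component_index(solution, locus)])

    def raw_score(self, solution) -> float:
        """Mean payoff contribution over all loci, in [0, 1)."""
        bits = self._check_solution(solution)
        total = 0.0
        for i in range(self.n_loci):
            total += self.payoff_tables[i, self.component_index(bits, i)]
        return total / self.n_loci

    def normalized_score(self, solution) -> float:
        """``(raw / raw_global_max) ** exponent``; the global optimum maps to 1."""
        if self.raw_global_max is None:
            raise RuntimeError("raw_global_max is unset; enumerate the landscape first")
        return float((self.raw_score(solution) / self.raw_global_max) ** self.exponent)

    # -- bulk enumeration -----------------------------------------------------

    def raw_table(self) -> np.ndarray:
        """Raw scores of all ``2**N`` solutions, indexed by integer encoding."""
        if self._raw_table is None:
            if self.n_loci > self.enumeration_cap:
                raise CapacityError(
                    f"N={self.n_loci} exceeds enumeration cap {self.enumeration_cap}"
                )
            if _HAVE_NUMBA:
                self._raw_table = _raw_table_numba(
                    self.n_loci, self.k_epistasis, self.partners, self.payoff_tables
                )
            else:
                self._raw_table = _raw_table_numpy(
                    self.n_loci, self.k_epistasis, self.partners, self.payoff_tables
                )
        return self._raw_table

    def normalized_table(self) -> np.ndarray:
        """Normalized scores of all ``2**N`` solutions (cached)."""
        if self._norm_table is None:
            raw = self.raw_table()
            if self.raw_global_max is None:
                self.raw_global_max = float(raw.max())
            self._norm_table = (raw / self.raw_global_max) ** self.exponent
        return self._norm_table

    def normalized_from_index(self, index):
        """Normalized score(s) for integer-encoded solution(s)."""
        return self.normalized_table()[index]

    def free_tables(self) -> None:
        """Drop the cached 2**N score tables (they are recomputable)."""
        self._raw_table = None
        self._norm_table = None


def enumerate_global_max(landscape: NKLandscape) -> tuple[np.ndarray, float]:
    """Exhaustive argmax/max of the raw score over all ``2**N`` solutions.

    Ties (probability zero under continuous payoffs) break toward the lowest
    integer encoding.  Also populates ``landscape.raw_global_max``.
    """
    raw = landscape.raw_table()
    best = int(np.argmax(raw))  # first occurrence == lowest integer encoding
    value = float(raw[best])
    if landscape.raw_global_max is None:
        landscape.raw_global_max = value
    return index_to_bits(best, landscape.n_loci), value


def generate_landscape(
    n_loci: int,
    k_epistasis: int,
    seed: int | None,
    exponent: float = DEFAULT_EXPONENT,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> NKLandscape:
    """Draw a random NK landscape and enumerate its global maximum.

    Partner sets are sampled uniformly without replacement among the other
    ``N-1`` loci; payoffs are uniform on [0, 1).  Reconstruction from
    ``(n_loci, k_epistasis, seed)`` is bit-identical: partners are drawn
    locus by locus, then all payoff tables in one block.
    """
    if n_loci < 1:
        raise ParameterError("n_loci must be >= 1")
    if not 0 <= k_epistasis <= n_loci - 1:
        raise ParameterError("k_epistasis must satisfy 0 <= K <= N-1")
    if n_loci > enumeration_cap:
        raise CapacityError(f"N={n_loci} exceeds enumeration cap {enumeration_cap}")
    rng = np.random.default_rng(seed)
    loci = np.arange(n_loci)
    partners = np.empty((n_loci, k_epistasis), dtype=np.int64)
    for i in range(n_loci):
        partners[i] = rng.choice(np.delete(loci, i), size=k_epistasis, replace=False)
    tables = rng.random((n_loci, 1 << (k_epistasis + 1)))
    land = NKLandscape(
        n_loci=n_loci,
        k_epistasis=k_epistasis,
        partners=partners,
        payoff_tables=tables,
        exponent=exponent,
        seed=seed,
        enumeration_cap=enumeration_cap,
    )
    enumerate_global_max(land)
    return land


# ---------------------------------------------------------------------------
# text serialization


def write_landscape(landscape: NKLandscape, path: str | os.PathLike) -> None:
    """Write the native single-file text format (full decimal precision)."""
    lines = [
        _FORMAT_MAGIC,
        f"n_loci {landscape.n_loci}",
        f"k_epistasis {landscape.k_epistasis}",
        f"exponent {landscape.exponent!r}",
        f"seed {'none' if landscape.seed is None else landscape.seed}",
        f"raw_global_max {'none' if landscape.raw_global_max is None else repr(landscape.raw_global_max)}",
    ]
    for i in range(landscape.n_loci):
        lines.append(
            f"partners {i} " + " ".join(str(p) for p in landscape.partners[i])
        )
    for i in range(landscape.n_loci):
        lines.append(
            f"table {i} " + " ".join(repr(float(v)) for v in landscape.payoff_tables[i])
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_field(lines: list[str], lineno: int, key: str) -> str:
    try:
        line = lines[lineno]
    except IndexError:
        raise LandscapeFormatError(f"line {lineno + 1}: missing '{key}' line") from None
    if line == key:
        return ""
    if not line.startswith(key + " "):
        raise LandscapeFormatError(f"line {lineno + 1}: expected '{key}', got {line!r}")
    return line[len(key) + 1 :]


def read_landscape(path: str | os.PathLike) -> NKLandscape:
    """Read the native text format written by :func:`write_landscape`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _FORMAT_MAGIC:
        raise LandscapeFormatError(f"line 1: bad or missing magic header ({_FORMAT_MAGIC})")
    try:
        n = int(_parse_field(lines, 1, "n_loci"))
        k = int(_parse_field(lines, 2, "k_epistasis"))
        exponent = float(_parse_field(lines, 3, "exponent"))
        seed_s = _parse_field(lines, 4, "seed")
        seed = None if seed_s == "none" else int(seed_s)
        gmax_s = _parse_field(lines, 5, "raw_global_max")
        gmax = None if gmax_s == "none" else float(gmax_s)
    except ValueError as exc:
        raise LandscapeFormatError(f"header parse error: {exc}") from exc
    partners = np.empty((n, k), dtype=np.int64)
    tables = np.empty((n, 1 << (k + 1)), dtype=np.float64)
    for i in range(n):
        row = _parse_field(lines, 6 + i, f"partners {i}").split()
        if len(row) != k:
            raise LandscapeFormatError(
                f"line {7 + i}: expected {k} partners for locus {i}, got {len(row)}"
            )
        partners[i] = [int(x) for x in row]
    for i in range(n):
        row = _parse_field(lines, 6 + n + i, f"table {i}").split()
        if len(row) != tables.shape[1]:
            raise LandscapeFormatError(
                f"line {7 + n + i}: expected {tables.shape[1]} payoffs for locus {i},"
                f" got {len(row)}"
            )
        tables[i] = [float(x) for x in row]
    return NKLandscape(
        n_loci=n,
        k_epistasis=k,
        partners=partners,
        payoff_tables=tables,
        exponent=exponent,
        seed=seed,
        raw_global_max=gmax,
    )


def export_enumeration(landscape: NKLandscape, path: str | os.PathLike) -> None:
    """Export the exhaustive dump: one line per solution, ``bitstring score``.

    Lines are ordered by integer encoding; scores are normalized.
    """
    norm = landscape.normalized_table()
    n = landscape.n_loci
    with open(path, "w") as fh:
        for s in range(1 << n):
            fh.write(f"{bits_to_string(index_to_bits(s, n))} {float(norm[s])!r}\n")
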