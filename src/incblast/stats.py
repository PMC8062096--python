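"""Significance statistics for local alignment searches over changing databases.

The expect value (e-value) of an alignment scales with the effective search
space, which in turn depends on the size of the database searched.  When a
database grows, or when a search is split across disjoint database partitions,
the e-values reported against each part are wrong for the whole.  This module
implements the two correction paths used by the NCBI BLAST family:

* Karlin-Altschul statistics (blastn, tblastx): recompute the length
  adjustment ``l`` for the union database by solving its fixed-point equation,
  then recompute ``E = K·m'·n'·e^(−λS)`` from the raw score — or, equivalently,
  add the contribution of the extra search space,
  ``E_total = E_part + K·e^(−λS)·(D_total − D_part)``.
* Spouge finite-size-correction statistics (blastp, blastx, tblastn): the
  finite-size "area" term depends only on the query and the scoring system,
  so e-values rescale by the ratio of actual database lengths,
  ``E_total = E_part · n_total/n_part``.

All e-values are carried as natural logarithms (:class:`EValue`); linear
values are produced only at serialization time, so quantities far below the
double-precision floor (and below the e^-180 level at which BLAST output
rounds to 0.0) remain exact and recoverable.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

__all__ = [
    "DomainError",
    "ZeroRoundedEValueError",
    "EValue",
    "KarlinParams",
    "QueryProfile",
    "DatabaseProfile",
    "SearchSpace",
    "compute_length_adjustment",
    "evalue_from_score",
    "correct_evalue_ka",
    "rescale_evalue_spouge",
    "growth_fraction",
    "percent_of",
    "projected_speedup",
    "statistics_family",
    "lookup_alpha_beta",
    "load_parameter_table",
    "format_evalue",
    "parse_evalue",
]

LN10 = math.log(10.0)

#: Natural-log threshold below which NCBI BLAST's decimal output collapses to
#: 0.0; values this small must be regenerated from raw scores, never parsed
#: back from a rounded document.
ZERO_ROUND_LOG_THRESHOLD = -180.0


class DomainError(ValueError):
    """An input is outside the mathematical domain of an operation."""


class ZeroRoundedEValueError(DomainError):
    """A zero-rounded e-value reached an operation that needs a true value.

    E-values parsed as exactly 0.0 carry no magnitude information; they must
    be regenerated from their raw score via the score formula against the
    appropriate search space instead of being corrected or rescaled.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EValue:
    """An expect value stored canonically as its natural logarithm.

    ``zero_rounded`` marks values that some upstream tool had already rounded
    to a literal 0.0: their magnitude is unknown (only that it was below the
    tool's printable range) and they must be regenerated from the raw score
    before any correction.
    """

    log_e: float
    zero_rounded: bool = False

    @classmethod
    def from_linear(cls, value: float) -> "EValue":
        if value < 0:
            raise DomainError(f"e-value must be >= 0, got {value}")
        if value == 0.0:
            return cls(log_e=-math.inf, zero_rounded=True)
        return cls(log_e=math.log(value))

    @classmethod
    def from_log(cls, log_e: float) -> "EValue":
        return cls(log_e=log_e)

    @property
    def linear(self) -> float:
        """The linear e-value; may underflow to 0.0 for display only."""
        return math.exp(self.log_e)

    def __lt__(self, other: "EValue") -> bool:
        return self.log_e < other.log_e


@dataclass(frozen=True)
class KarlinParams:
    """Statistical parameters of a scoring system.

    lambda_ : per-score decay rate of the score distribution (nats/score unit)
    K       : search-space scale constant (dimensionless)
    H       : relative entropy of the scoring system (nats/aligned pair)
    alpha   : slope term of the length-adjustment equation (dimensionless)
    beta    : intercept of the length-adjustment equation (residues)
    """

    lambda_: float
    K: float
    H: Optional[float] = None
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not self.lambda_ > 0:
            raise DomainError(f"lambda must be > 0, got {self.lambda_}")
        if not self.K > 0:
            raise DomainError(f"K must be > 0, got {self.K}")
        if self.H is not None and not self.H > 0:
            raise DomainError(f"H must be > 0 when present, got {self.H}")
        if self.alpha < 0:
            raise DomainError(f"alpha must be >= 0, got {self.alpha}")


@dataclass(frozen=True)
class QueryProfile:
    """A query sequence's identity and actual length m in residues."""

    query_id: str
    m: int

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise DomainError(f"query length m must be > 0, got {self.m}")


@dataclass(frozen=True)
class DatabaseProfile:
    """Identity and size of one database instance at a point in time.

    ``db_id`` is a stable identifier for the database lineage (e.g. "nt");
    snapshots of the same database at different times share it.  ``n`` is the
    total residue/base count, ``N`` the number of sequences, ``files`` the
    ordered member volume list.
    """

    db_id: str
    n: int
    N: int
    files: tuple = ()
    molecule: str = "nucleotide"  # nucleotide | protein
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.n < 0 or self.N < 0:
            raise DomainError("database sizes must be non-negative")
        if (self.n or self.N) and self.n < self.N:
            raise DomainError(
                f"n ({self.n}) < N ({self.N}): every sequence has >= 1 residue"
            )
        if self.molecule not in ("nucleotide", "protein"):
            raise DomainError(f"unknown molecule type {self.molecule!r}")
        files = tuple(self.files)
        if len(set(files)) != len(files):
            raise DomainError("database volume list contains duplicates")
        object.__setattr__(self, "files", files)


@dataclass(frozen=True)
class SearchSpace:
    """Edge-effect-corrected search space for one (query, database) pair.

    l is the length adjustment; effective lengths are m' = m − l and
    n' = n − N·l; D = m'·n' is the effective search space.
    """

    l: int
    m_eff: int
    n_eff: int
    D: int = field(default=0)

    def __post_init__(self) -> None:
        if self.l < 0:
            raise DomainError(f"length adjustment must be >= 0, got {self.l}")
        if self.m_eff <= 0 or self.n_eff <= 0:
            raise DomainError(
                f"effective lengths must be positive (m'={self.m_eff}, n'={self.n_eff})"
            )
        if self.D == 0:
            object.__setattr__(self, "D", self.m_eff * self.n_eff)
        elif self.D != self.m_eff * self.n_eff:
            raise DomainError("D must equal m_eff * n_eff exactly")


# ---------------------------------------------------------------------------
# Length adjustment (fixed-point equation)
# ---------------------------------------------------------------------------


def _length_adjustment_rhs(
    params: KarlinParams, m: int, n: int, N: int, l: float
) -> float:
    # f(l) = (alpha/lambda) * ln(K (m-l)(n-Nl)) + beta; decreasing in l on its domain
    return (params.alpha / params.lambda_) * math.log(
        params.K * (m - l) * (n - N * l)
    ) + params.beta


def compute_length_adjustment(
    params: KarlinParams, query: QueryProfile, db: DatabaseProfile
) -> SearchSpace:
    """Solve the length-adjustment fixed-point equation for (query, db).

    Finds the saturating integer solution of

        l = (alpha/lambda) * ln(K * (m - l) * (n - N*l)) + beta

    i.e. the largest integer ``l`` with ``l <= f(l)`` (``f`` is decreasing on
    its domain, so this is the floor of the real fixed point), clamped so the
    effective lengths m − l and n − N·l stay >= 1.  A real-valued fixed-point
    iteration (at most 20 steps, converged when successive iterates differ by
    less than 1) locates the neighbourhood; an explicit integer saturation
    step then pins the exact value.
    """
    m, n, N = query.m, db.n, db.N
    if n <= 0 or N <= 0:
        raise DomainError(f"database must be non-empty (n={n}, N={N})")

    # Largest l keeping both effective lengths >= 1.
    l_max = min(m - 1, (n - 1) // N)
    if l_max < 0:
        raise DomainError(
            f"no length adjustment keeps effective lengths positive (m={m}, n={n}, N={N})"
        )

    def f(l: float) -> float:
        return _length_adjustment_rhs(params, m, n, N, l)

    if params.alpha == 0.0:
        # Iteration is the constant beta.
        l = int(min(max(math.floor(params.beta), 0), l_max))
    else:
        x = 0.0
        for _ in range(20):
            nxt = f(min(max(x, 0.0), float(l_max)))
            nxt = min(max(nxt, 0.0), float(l_max))
            if abs(nxt - x) < 1.0:
                x = nxt
                break
            x = nxt
        l = int(min(max(math.floor(x), 0), l_max))
        # Saturation: largest integer l with l <= f(l) (f decreasing).
        while l < l_max and (l + 1) <= f(float(l + 1)):
            l += 1
        while l > 0 and l > f(float(l)):
            l -= 1

    return SearchSpace(l=l, m_eff=m - l, n_eff=n - N * l)


# ---------------------------------------------------------------------------
# E-value computation and correction
# ---------------------------------------------------------------------------


def evalue_from_score(
    params: KarlinParams, space: SearchSpace, score: float
) -> EValue:
    """E = K · m' · n' · e^(−λS), computed entirely in log space."""
    log_e = math.fsum(
        (
            math.log(params.K),
            math.log(space.m_eff),
            math.log(space.n_eff),
            -params.lambda_ * score,
        )
    )
    return EValue(log_e=log_e)


def correct_evalue_ka(
    params: KarlinParams,
    e_part: EValue,
    score: float,
    D_part: int,
    D_total: int,
) -> EValue:
    """Additive Karlin-Altschul correction for an enlarged search space.

    E_total = E_part + K·e^(−λS)·(D_total − D_part).  Equivalent (to rounding)
    to recomputing E = K·D_total·e^(−λS) from scratch when ``e_part`` is
    itself consistent with D_part.
    """
    if e_part.zero_rounded:
        raise ZeroRoundedEValueError(
            "zero-rounded e-value cannot be corrected; recompute it from the "
            "raw score with evalue_from_score"
        )
    if D_part <= 0:
        raise DomainError(f"D_part must be > 0, got {D_part}")
    if D_total < D_part:
        raise DomainError(
            f"database shrank (D_total={D_total} < D_part={D_part}); "
            "additive correction is undefined"
        )
    if D_total == D_part:
        return e_part
    log_increment = math.log(params.K) - params.lambda_ * score + math.log(
        D_total - D_part
    )
    # log-sum-exp of the two contributions
    hi = max(e_part.log_e, log_increment)
    lo = min(e_part.log_e, log_increment)
    return EValue(log_e=hi + math.log1p(math.exp(lo - hi)))


def rescale_evalue_spouge(e_part: EValue, n_part: int, n_total: int) -> EValue:
    """Spouge-statistics rescaling: E_total = E_part · n_total / n_part.

    The finite-size-correction "area" depends only on the query and scoring
    system, so under a database size change only the database scale factor
    moves; in log space the rescale is exact.
    """
    if e_part.zero_rounded:
        raise ZeroRoundedEValueError(
            "zero-rounded e-value cannot be rescaled; recompute it from the "
            "raw score with evalue_from_score against the part search space"
        )
    if n_part <= 0 or n_total <= 0:
        raise DomainError(
            f"database lengths must be > 0 (n_part={n_part}, n_total={n_total})"
        )
    # ratio first, so n_total == n_part is the exact identity
    return EValue(log_e=e_part.log_e + (math.log(n_total) - math.log(n_part)))


# ---------------------------------------------------------------------------
# Size / growth / speedup arithmetic
# ---------------------------------------------------------------------------


def _truncate(value: float, ndigits: int) -> float:
    scale = 10.0 ** ndigits
    # tiny nudge guards against 40.89999... representations of exact decimals
    return math.floor(value * scale + 1e-9) / scale


def growth_fraction(past_size: float, present_size: float) -> float:
    """Database growth from ``past_size`` to ``present_size`` as a percentage.

    Returns 100·(present − past)/past truncated to one decimal place, the
    precision at which growth figures are conventionally reported.
    """
    if past_size <= 0:
        raise DomainError(f"past size must be > 0, got {past_size}")
    if present_size < past_size:
        raise DomainError("database shrank; growth fraction undefined")
    return _truncate(100.0 * (present_size - past_size) / past_size, 1)


def percent_of(part: float, whole: float, ndigits: int = 2) -> float:
    """100·part/whole truncated to ``ndigits`` decimals."""
    if whole <= 0:
        raise DomainError(f"whole must be > 0, got {whole}")
    if part < 0:
        raise DomainError(f"part must be >= 0, got {part}")
    return _truncate(100.0 * part / whole, ndigits)


def projected_speedup(delta: float) -> float:
    """Projected speedup (1 + δ)/δ of searching only the grown fraction δ.

    Searching the delta alone costs δ of a full search that would cost 1 + δ
    relative to the prior database, hence the ratio.
    """
    if delta <= 0:
        raise DomainError(f"growth fraction delta must be > 0, got {delta}")
    return (1.0 + delta) / delta


# ---------------------------------------------------------------------------
# Statistics-family routing and parameter provenance
# ---------------------------------------------------------------------------

_KA_PROGRAMS = frozenset({"blastn", "tblastx"})
_SPOUGE_PROGRAMS = frozenset({"blastp", "blastx", "tblastn"})


def statistics_family(program: str) -> str:
    """Which statistics family a BLAST program uses for its e-values.

    blastn and tblastx use Karlin-Altschul statistics; blastp, blastx and
    tblastn use Spouge finite-size-correction statistics.
    """
    p = program.lower()
    if p in _KA_PROGRAMS:
        return "karlin-altschul"
    if p in _SPOUGE_PROGRAMS:
        return "spouge"
    raise DomainError(f"unknown BLAST program {program!r}")


@dataclass(frozen=True)
class _ParamRow:
    lambda_: float
    K: float
    H: float
    alpha: float
    beta: float


def load_parameter_table(path=None) -> dict:
    """Load the (program, scoring scheme) -> Karlin parameter lookup table.

    The bundled table is transcribed from NCBI's published gapped/ungapped
    parameter tables; pass ``path`` to override it with a user table of the
    same tab-separated layout.
    """
    if path is None:
        source = resources.files("incblast").joinpath("data/karlin_params.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    table = {}
    reader = csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#")),
        delimiter="\t",
    )
    for row in reader:
        key = (
            row["program"].lower(),
            row["matrix"].upper(),
            int(row["mismatch"]) if row["mismatch"] != "." else None,
            int(row["gap_open"]),
            int(row["gap_extend"]),
        )
        table[key] = _ParamRow(
            lambda_=float(row["lambda"]),
            K=float(row["K"]),
            H=float(row["H"]),
            alpha=float(row["alpha"]),
            beta=float(row["beta"]),
        )
    return table


_TABLE_CACHE: Optional[dict] = None


def _table() -> dict:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = load_parameter_table()
    return _TABLE_CACHE


def lookup_alpha_beta(
    program: str,
    *,
    matrix: Optional[str] = None,
    match: Optional[int] = None,
    mismatch: Optional[int] = None,
    gap_open: int = 0,
    gap_extend: int = 0,
    lambda_: Optional[float] = None,
    K: Optional[float] = None,
    H: Optional[float] = None,
    table: Optional[dict] = None,
) -> KarlinParams:
    """Resolve full Karlin parameters for a scoring scheme.

    λ, K and H normally travel inside each result's own statistics block and,
    when given, take precedence over the table; α and β are not serialized by
    BLAST and come from the bundled lookup table keyed by
    (program, matrix or match score, mismatch, gap_open, gap_extend).

    For scoring schemes absent from the table the ungapped convention
    α = λ/H, β = 0 is used and a warning is emitted.
    """
    tbl = table if table is not None else _table()
    scoring = matrix.upper() if matrix is not None else str(match)
    key = (program.lower(), scoring, mismatch, gap_open, gap_extend)
    row = tbl.get(key)
    if row is not None:
        return KarlinParams(
            lambda_=lambda_ if lambda_ is not None else row.lambda_,
            K=K if K is not None else row.K,
            H=H if H is not None else row.H,
            alpha=row.alpha,
            beta=row.beta,
        )
    if lambda_ is None or K is None:
        raise DomainError(
            f"scoring scheme {key} not in parameter table and no lambda/K supplied"
        )
    if H is not None and H > 0:
        alpha = lambda_ / H
    else:
        alpha = 0.0
    warnings.warn(
        f"scoring scheme {key} not in parameter table; falling back to the "
        f"ungapped convention alpha = lambda/H = {alpha:.4g}, beta = 0",
        stacklevel=2,
    )
    return KarlinParams(lambda_=lambda_, K=K, H=H, alpha=alpha, beta=0.0)


# ---------------------------------------------------------------------------
# E-value serialization helpers
# ---------------------------------------------------------------------------


def format_evalue(ev: EValue, sig: int = 13) -> str:
    """Render an e-value as a decimal string without ever printing 0.0.

    The mantissa/exponent pair is derived from log10(E) directly, so values
    far below the double-precision floor (well past the e^-180 level at which
    standard BLAST output collapses to 0.0) serialize faithfully.  A
    zero-rounded input (one that was already 0.0 upstream) round-trips as
    "0.0" to preserve its flag.
    """
    if ev.zero_rounded:
        return "0.0"
    log10e = ev.log_e / LN10
    exponent = math.floor(log10e)
    mantissa = 10.0 ** (log10e - exponent)
    # guard against mantissa rounding up to 10 at the printed precision
    if round(mantissa, sig - 1) >= 10.0:
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.{sig - 1}f}e{exponent:+03d}"


def parse_evalue(text: str) -> EValue:
    """Parse a decimal e-value string into log space.

    A literal zero (``0``, ``0.0``, ``0e+00``...) is flagged as zero-rounded:
    its true magnitude is unknown and downstream corrections must regenerate
    it from the raw score.  The mantissa and exponent are combined in log
    space, so tiny values never pass through a linear double.
    """
    s = text.strip()
    if "e" in s or "E" in s:
        mant_s, _, exp_s = s.replace("E", "e").partition("e")
        mant = float(mant_s)
        if mant == 0.0:
            return EValue(log_e=-math.inf, zero_rounded=True)
        if mant < 0:
            raise DomainError(f"negative e-value {text!r}")
        return EValue(log_e=math.log(mant) + int(exp_s) * LN10)
    value = float(s)
    if value == 0.0:
        return EValue(log_e=-math.inf, zero_rounded=True)
    if value < 0:
        raise DomainError(f"negative e-value {text!r}")
    return EValue(log_e=math.log(value))
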