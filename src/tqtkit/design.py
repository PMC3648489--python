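"""Williams crossover designs, randomisation, session accounting and design-based power.

The central object is the five-period crossover with two placebo periods:
replicating the placebo reference halves its variance contribution to every
active-vs-placebo contrast, so the same power is reached with fewer subjects
than the conventional four-period single-placebo layout.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

PLACEBO = "placebo"

#: Active treatment labels, in the order they are attached to non-placebo symbols.
DEFAULT_ACTIVE_TREATMENTS = ("therapeutic", "supratherapeutic", "control")

#: Variance multiplier k of the placebo-corrected contrast: Var = k * sigma^2 / n,
#: where sigma^2 is the per-period change-from-baseline variance.
VARIANCE_FACTOR = {"single_placebo_4p": 2.0, "double_placebo_5p": 1.5}

N_PERIODS = {"single_placebo_4p": 4, "double_placebo_5p": 5}
N_PLACEBO_PERIODS = {"single_placebo_4p": 1, "double_placebo_5p": 2}

#: Correlation between the two dose-vs-placebo test statistics induced by the
#: shared (averaged) placebo term: Cov = Var(placebo mean) = 0.5*sigma^2,
#: Var(each contrast) = 1.5*sigma^2, hence rho = 1/3.
SHARED_PLACEBO_CORRELATION = 1.0 / 3.0


class DesignError(ValueError):
    """Raised when a crossover design violates one of its invariants."""


class InfeasibleAssignmentError(DesignError):
    """Raised when no placebo-symbol assignment satisfies the placement constraint."""


@dataclass(frozen=True)
class CrossoverDesign:
    """A sequences-by-periods treatment layout.

    Parameters
    ----------
    symbols
        Ordered treatment symbols, e.g. ``("A", ..., "E")``.
    sequences
        Period-ordered symbol tuples, one per sequence (row).
    symbol_to_treatment
        Optional mapping from symbol to treatment label.  For the five-period
        double-placebo variant exactly two symbols map to ``"placebo"``.
    block_size
        Randomisation blocking factor (defaults to the number of sequences).
    """

    symbols: tuple[str, ...]
    sequences: tuple[tuple[str, ...], ...]
    symbol_to_treatment: dict[str, str] | None = None
    block_size: int = 0

    def __post_init__(self) -> None:
        if self.block_size == 0:
            object.__setattr__(self, "block_size", len(self.sequences))

    @property
    def n_periods(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def placebo_symbols(self) -> tuple[str, ...]:
        if self.symbol_to_treatment is None:
            return ()
        return tuple(s for s, t in self.symbol_to_treatment.items() if t == PLACEBO)

    def treatments_for(self, sequence_index: int) -> tuple[str, ...]:
        """Treatment labels of one sequence, in period order."""
        if self.symbol_to_treatment is None:
            raise DesignError("no symbol-to-treatment assignment set")
        return tuple(self.symbol_to_treatment[s] for s in self.sequences[sequence_index])

    def validate(self) -> None:
        """Check Latin rows, column balance, first-order carryover balance and,
        if a double-placebo assignment is present, the placebo-placement rule.

        Raises :class:`DesignError` on the first violated invariant.
        """
        n = len(self.symbols)
        for seq in self.sequences:
            if len(seq) != self.n_periods or set(seq) != set(self.symbols):
                raise DesignError(f"sequence {seq} is not a permutation of the symbols")
        # column balance
        for p in range(self.n_periods):
            counts = pd.Series([seq[p] for seq in self.sequences]).value_counts()
            if counts.nunique() != 1 or len(counts) != n:
                raise DesignError(f"period {p + 1} is not balanced across symbols")
        # Williams first-order carryover balance
        pair_counts: dict[tuple[str, str], int] = {}
        for seq in self.sequences:
            for a, b in zip(seq, seq[1:]):
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
        expected = len(self.sequences) * (self.n_periods - 1) / (n * (n - 1))
        for a in self.symbols:
            for b in self.symbols:
                if a != b and pair_counts.get((a, b), 0) != expected:
                    raise DesignError(
                        f"ordered pair {a}->{b} occurs {pair_counts.get((a, b), 0)} "
                        f"times consecutively, expected {expected}"
                    )
        if self.symbol_to_treatment is not None and len(self.placebo_symbols) == 2:
            bad = _placebo_placement_violations(self.sequences, self.placebo_symbols)
            if bad:
                raise DesignError(
                    f"sequences {bad} carry both placebo symbols in the first "
                    "two or last two periods"
                )


def _placebo_placement_violations(
    sequences: tuple[tuple[str, ...], ...], placebo_symbols: tuple[str, ...]
) -> list[int]:
    pset = set(placebo_symbols)
    bad = []
    for i, seq in enumerate(sequences):
        if pset <= set(seq[:2]) or pset <= set(seq[-2:]):
            bad.append(i)
    return bad


def generate_williams_design(n_symbols: int) -> CrossoverDesign:
    """Generate a Williams design balanced for first-order carryover.

    Uses the standard interleaved construction: first row
    ``0, 1, n-1, 2, n-2, ...`` with cyclic shifts; for odd ``n_symbols`` the
    mirror image of the square is appended, giving ``2n`` sequences (``n``
    sequences for even ``n_symbols``).
    """
    if n_symbols < 2:
        raise ValueError("n_symbols must be >= 2")
    symbols = tuple(string.ascii_uppercase[:n_symbols])
    row0 = [
        0 if j == 0 else ((j + 1) // 2 if j % 2 == 1 else n_symbols - j // 2)
        for j in range(n_symbols)
    ]
    rows = [[(x + i) % n_symbols for x in row0] for i in range(n_symbols)]
    if n_symbols % 2 == 1:
        rows += [list(reversed(r)) for r in rows]
    sequences = tuple(tuple(symbols[x] for x in row) for row in rows)
    design = CrossoverDesign(symbols=symbols, sequences=sequences)
    design.validate()
    return design


def assign_placebo_symbols(
    design: CrossoverDesign,
    n_placebo_symbols: int = 2,
    active_treatments: tuple[str, ...] = DEFAULT_ACTIVE_TREATMENTS,
) -> CrossoverDesign:
    """Attach treatments to symbols so that no sequence carries both placebo
    symbols in the first two or the last two periods.

    The feasible symbol pair is found by brute force over all
    ``C(n_symbols, n_placebo_symbols)`` combinations in lexicographic order
    (deterministic tie-break: first feasible combination wins).

    Raises
    ------
    InfeasibleAssignmentError
        If no symbol combination satisfies the placement constraint.
    ValueError
        If the number of active treatments does not fill the remaining symbols.
    """
    n_active = len(design.symbols) - n_placebo_symbols
    if n_active < 0:
        raise InfeasibleAssignmentError(
            f"cannot place {n_placebo_symbols} placebo symbols on "
            f"{len(design.symbols)} symbols"
        )
    if n_active != len(active_treatments):
        raise ValueError(
            f"{n_active} non-placebo symbols but {len(active_treatments)} "
            "active treatment labels"
        )
    for combo in combinations(design.symbols, n_placebo_symbols):
        if n_placebo_symbols < 2 or not _placebo_placement_violations(design.sequences, combo):
            mapping = {s: PLACEBO for s in combo}
            rest = [s for s in design.symbols if s not in combo]
            mapping.update(dict(zip(rest, active_treatments)))
            out = replace(design, symbol_to_treatment=mapping)
            out.validate()
            return out
    raise InfeasibleAssignmentError(
        "every symbol combination places both placebos in the first two or "
        "last two periods of at least one sequence"
    )


def randomise(design: CrossoverDesign, n_subjects: int, seed: int) -> pd.DataFrame:
    """Allocate subjects to sequences in blocks of ``design.block_size``.

    Within each complete block every sequence is used exactly once (random
    order); a final partial block draws a random subset of sequences and is
    flagged in the ``partial_block`` column.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    nseq = design.n_sequences
    block = design.block_size
    if block != nseq:
        raise DesignError("block size must equal the number of sequences")
    rows = []
    subject = 0
    block_index = 0
    while subject < n_subjects:
        perm = rng.permutation(nseq)
        take = min(block, n_subjects - subject)
        partial = take < block
        for j in range(take):
            subject += 1
            seq_idx = int(perm[j])
            row = {
                "subject_id": f"S{subject:03d}",
                "block": block_index + 1,
                "sequence_index": seq_idx,
                "sequence": "".join(design.sequences[seq_idx]),
                "partial_block": partial,
            }
            if design.symbol_to_treatment is not None:
                for p, trt in enumerate(design.treatments_for(seq_idx), start=1):
                    row[f"period_{p}"] = trt
            rows.append(row)
        block_index += 1
    return pd.DataFrame(rows)


def count_sessions(design_type: str, n_subjects: int) -> dict[str, int]:
    """Per-treatment and total session counts for a design type.

    Each subject contributes one session per period; placebo gets one session
    per placebo period per subject, every active treatment one per subject.
    """
    if design_type not in N_PERIODS:
        raise ValueError(f"unknown design_type {design_type!r}")
    n_periods = N_PERIODS[design_type]
    n_placebo = N_PLACEBO_PERIODS[design_type]
    out = {"placebo_sessions": n_subjects * n_placebo}
    for trt in DEFAULT_ACTIVE_TREATMENTS:
        out[f"{trt}_sessions"] = n_subjects
    out["total_sessions"] = n_subjects * n_periods
    return out


@dataclass(frozen=True)
class PowerAssumptions:
    """Assumptions of the sample-size/power calculus.

    ``endpoint_sd`` is the standard deviation of the within-subject difference
    between one active-period and one placebo-period change from baseline, so
    the per-period change-from-baseline variance is ``endpoint_sd**2 / 2``.
    """

    true_difference: float = 2.0
    endpoint_sd: float = 14.0
    margin: float = 10.0
    alpha_one_sided: float = 0.05
    per_dose_power_target: float = 0.95
    overall_power_target: float = 0.90
    reference_single_placebo_completers: int = 36
    dropout_allowance: int = 3
    superiority_effect: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_one_sided < 0.5:
            raise ValueError("alpha_one_sided must be in (0, 0.5)")
        if not self.margin > self.true_difference >= 0:
            raise ValueError("need margin > true_difference >= 0")
        if self.endpoint_sd <= 0:
            raise ValueError("endpoint_sd must be positive")

    @property
    def per_period_cfb_variance(self) -> float:
        return self.endpoint_sd**2 / 2.0


@dataclass(frozen=True)
class PowerEstimate:
    """Analytic power of the placebo-corrected margin test."""

    design_type: str
    n_completers: int
    se: float
    per_dose_power: float
    overall_power: float
    control_superiority_power: float
    use_t: bool


def contrast_se(n_completers: int, design_type: str, assumptions: PowerAssumptions) -> float:
    """Standard error of the placebo-corrected contrast: sqrt(k*sigma^2/n)."""
    k = VARIANCE_FACTOR[design_type]
    return math.sqrt(k * assumptions.per_period_cfb_variance / n_completers)


def analytic_power(
    n_completers: int,
    design_type: str,
    assumptions: PowerAssumptions | None = None,
    use_t: bool = True,
    overall_method: str = "bivariate",
) -> PowerEstimate:
    """Closed-form power of the one-sided margin test (and the positive-control
    superiority test) in either design.

    Per-dose power is the probability that the upper one-sided bound of the
    placebo-corrected contrast falls below the margin.  With ``use_t`` the
    rejection region uses the t critical value with ``n_completers - 1``
    degrees of freedom and power is evaluated under the noncentral t; otherwise
    a plain normal model is used.

    Overall power (both dose tests rejecting simultaneously) is computed as a
    bivariate normal probability with correlation 1/3 from the shared placebo
    term, or as the independence product when
    ``overall_method='independent'`` (documented approximation; the shared
    placebo makes the tests positively correlated, so the product is
    conservative).
    """
    if n_completers < 2:
        raise ValueError("n_completers must be >= 2")
    a = assumptions or PowerAssumptions()
    se = contrast_se(n_completers, design_type, a)
    df = n_completers - 1
    if use_t:
        crit = stats.t.ppf(1 - a.alpha_one_sided, df)
        per_dose = float(stats.nct.cdf(-crit, df, (a.true_difference - a.margin) / se))
        control = float(1 - stats.nct.cdf(crit, df, a.superiority_effect / se))
    else:
        crit = stats.norm.ppf(1 - a.alpha_one_sided)
        per_dose = float(stats.norm.cdf((a.margin - a.true_difference) / se - crit))
        control = float(stats.norm.cdf(a.superiority_effect / se - crit))
    if overall_method == "bivariate":
        # Normal-scale joint probability at the (possibly t) critical value.
        # Shared-placebo correlation: double placebo Cov=0.5s2/Var=1.5s2 -> 1/3;
        # single placebo Cov=s2/Var=2s2 -> 1/2.
        c = (a.margin - a.true_difference) / se - crit
        rho = SHARED_PLACEBO_CORRELATION if design_type == "double_placebo_5p" else 0.5
        overall = float(
            stats.multivariate_normal.cdf(
                [c, c], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            )
        )
    else:
        overall = per_dose**2
    return PowerEstimate(
        design_type=design_type,
        n_completers=n_completers,
        se=se,
        per_dose_power=per_dose,
        overall_power=overall,
        control_superiority_power=control,
        use_t=use_t,
    )


def required_sample_size(assumptions: PowerAssumptions | None = None) -> dict[str, int]:
    """Randomised sample size of the double-placebo five-period design.

    The minimal completer count ``n`` satisfies ``1.5*sigma^2/n <= 2*sigma^2/m``
    where ``m`` is the single-placebo reference completer count — i.e. the
    double-placebo contrast is at least as precise as the reference design —
    which reduces to ``n = ceil(0.75 * m)`` independent of sigma.  The
    randomised count adds the dropout allowance.
    """
    a = assumptions or PowerAssumptions()
    m = a.reference_single_placebo_completers
    n_completers = math.ceil(
        m * VARIANCE_FACTOR["double_placebo_5p"] / VARIANCE_FACTOR["single_placebo_4p"]
    )
    return {
        "completers": n_completers,
        "dropout_allowance": a.dropout_allowance,
        "randomised": n_completers + a.dropout_allowance,
        "reference_single_placebo_completers": m,
    }
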