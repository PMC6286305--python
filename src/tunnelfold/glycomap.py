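"""Glycosylation-mapping analysis.

Distance accounting for truncated nascent-chain constructs, two-band gel
quantification, replicate statistics, logistic profile fitting, the
critical-distance compaction statistic, and conversion of a d50 shift into
an estimated number of folded residues.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetics import GelDataset, logistic_law

__all__ = [
    "Construct",
    "GlycProfile",
    "SigmoidFit",
    "CompactionCall",
    "pnst_distance",
    "percent_glyc",
    "build_profile",
    "fit_sigmoid",
    "critical_stat",
    "infer_folded",
    "helix_span_residues",
    "compare_conditions",
    "gel_mass_model",
    "call_compaction",
]

D_CRITICAL = 67
D_FULL = 73
RISE_EXTENDED = 3.4  # Å per residue
RISE_HELICAL = 1.5  # Å per residue
PER_GLYCAN_SHIFT_KDA = 2.5


class ConstructError(ValueError):
    pass


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class Construct:
    """A truncated nascent chain with a single N-glycosylation acceptor.

    ``acceptor_position`` is the 1-based index of the Asn of the N-S-T
    sequon; the chain is truncated at ``truncation_length`` residues.
    """

    sequence: str
    acceptor_position: int
    truncation_length: int | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        length = self.truncation_length or len(seq)
        pos = self.acceptor_position
        if not (1 <= pos <= length):
            raise ConstructError("acceptor position outside the truncated chain")
        if length > len(seq):
            raise ConstructError("truncation length exceeds sequence length")
        if seq[pos - 1 : pos + 2] != "NST":
            raise ConstructError(
                f"no N-S-T acceptor motif at position {pos} "
                f"(found {seq[pos - 1: pos + 2]!r})"
            )

    @property
    def length(self) -> int:
        return self.truncation_length or len(self.sequence)


def pnst_distance(construct: Construct) -> int:
    """P-NST distance d: residues strictly C-terminal of the acceptor Asn."""
    return construct.length - construct.acceptor_position


def percent_glyc(glyc: float, nonglyc: float) -> float:
    """Two-band densitometry: 100·glyc/(glyc + nonglyc).  Scale-invariant."""
    if glyc < 0 or nonglyc < 0:
        raise QuantificationError("band intensities must be non-negative")
    total = glyc + nonglyc
    if total == 0:
        raise QuantificationError("both band intensities are zero")
    return 100.0 * glyc / total


@dataclass
class GlycProfile:
    """Per-distance summary of replicate percent-glycosylation values."""

    summary: pd.DataFrame  # columns: d, mean, sd, n
    replicates: pd.DataFrame  # columns: d, replicate, percent
    construct: str = "construct"

    def at(self, d: int) -> float:
        row = self.summary.loc[self.summary["d"] == d]
        if row.empty:
            raise KeyError(f"no data at d = {d}")
        return float(row["mean"].iloc[0])

    def replicate_values(self, d: int) -> np.ndarray:
        vals = self.replicates.loc[self.replicates["d"] == d, "percent"]
        return vals.to_numpy(dtype=float)


def build_profile(dataset: GelDataset, n_floor: int = 3) -> GlycProfile:
    """Summarize a tidy gel dataset into a per-d glycosylation profile.

    Means use all replicates; SD is the sample standard deviation (n − 1
    denominator) and is reported as NaN with a warning when n < 2.  A
    warning is also emitted for any d below the replicate floor.
    """
    table = dataset.table
    if table.empty:
        raise QuantificationError("empty gel dataset")
    wide = table.pivot_table(
        index=["construct", "d", "replicate"], columns="band",
        values="intensity", aggfunc="sum",
    ).reset_index()
    for band in ("glyc", "nonglyc"):
        if band not in wide.columns:
            raise QuantificationError(f"dataset lacks {band!r} band rows")
    wide["percent"] = [
        percent_glyc(g, n) for g, n in zip(wide["glyc"], wide["nonglyc"])
    ]
    construct = str(wide["construct"].iloc[0])

    rows = []
    for d, grp in wide.groupby("d"):
        vals = grp["percent"].to_numpy(dtype=float)
        n = len(vals)
        if n < n_floor:
            warnings.warn(
                f"d = {d}: only {n} replicate(s), below the n ≥ {n_floor} floor",
                stacklevel=2,
            )
        sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
        rows.append((d, float(vals.mean()), sd, n))
    summary = pd.DataFrame(rows, columns=["d", "mean", "sd", "n"]).sort_values("d")
    reps = wide[["d", "replicate", "percent"]].copy()
    return GlycProfile(summary=summary.reset_index(drop=True), replicates=reps,
                       construct=construct)


@dataclass
class SigmoidFit:
    d50: float
    slope: float
    g_min: float
    g_max: float
    rss: float
    converged: bool
    message: str = ""

    def predict(self, d) -> np.ndarray:
        return logistic_law(d, self.d50, self.slope, self.g_min, self.g_max)


def fit_sigmoid(
    profile: GlycProfile,
    use_replicates: bool = True,
    asymptote_bounds: tuple[float, float] | None = (15.0, 85.0),
) -> SigmoidFit:
    """Least-squares logistic fit of percent glycosylation against d.

    G(d) = G_min + (G_max − G_min)/(1 + exp(−(d − d50)/s)); initialized from
    the data range and the d nearest half-maximum, with bounded parameters.
    Non-convergence or a non-identifiable (flat) profile yields a flagged
    fit rather than an exception.

    ``asymptote_bounds = (g_min_max, g_max_min)`` constrains the baseline to
    [0, g_min_max] and the plateau to [g_max_min, 100].  The default (15, 85)
    encodes the assay's design premise — short constructs are essentially
    unglycosylated and sufficiently long ones fully glycosylated — and
    matters when the sampled d range covers only one flank of the
    transition, where a free baseline is weakly identified and lets d50
    drift.  Pass ``None`` for a fully free fit.
    """
    if use_replicates and not profile.replicates.empty:
        d = profile.replicates["d"].to_numpy(dtype=float)
        y = profile.replicates["percent"].to_numpy(dtype=float)
    else:
        d = profile.summary["d"].to_numpy(dtype=float)
        y = profile.summary["mean"].to_numpy(dtype=float)

    distinct = np.unique(d)
    flat = SigmoidFit(float("nan"), float("nan"), float(y.min(initial=0.0)),
                      float(y.max(initial=0.0)), float("nan"), False)
    if len(distinct) < 4:
        flat.message = "need ≥ 4 distinct d values"
        return flat
    if y.max() - y.min() < 5.0:
        flat.message = "profile is flat: transition not identifiable"
        return flat

    if asymptote_bounds is None:
        gmin_hi, gmax_lo = 100.0, 0.0
    else:
        gmin_hi, gmax_lo = asymptote_bounds
    g_lo, g_hi = float(y.min()), float(y.max())
    half = (g_lo + g_hi) / 2.0
    means = np.array([y[d == dv].mean() for dv in distinct])
    d50_init = float(distinct[np.argmin(np.abs(means - half))])
    p0 = [
        d50_init, 1.0,
        min(max(g_lo, 0.0), gmin_hi - 0.5),
        max(min(g_hi, 100.0), gmax_lo + 0.5),
    ]
    lower = [distinct.min() - 10.0, 0.05, 0.0, gmax_lo]
    upper = [distinct.max() + 10.0, 20.0, gmin_hi, 100.0]

    def model(dd, d50, s, gmin, gmax):
        return logistic_law(dd, d50, s, gmin, gmax)

    try:
        popt, _ = optimize.curve_fit(
            model, d, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        flat.message = f"fit failed: {exc}"
        return flat
    d50, s, gmin, gmax = (float(v) for v in popt)
    if gmax <= gmin:
        flat.message = "degenerate fit: G_max ≤ G_min"
        return flat
    resid = y - model(d, *popt)
    return SigmoidFit(d50, s, gmin, gmax, float(np.sum(resid ** 2)), True)


def critical_stat(
    profile: GlycProfile | None,
    fit: SigmoidFit | None = None,
    d_crit: int = D_CRITICAL,
    d_full: int = D_FULL,
) -> float:
    """Percentage-point glycosylation gap G(d_full) − G(d_crit).

    Large positive for compact chains (under-glycosylated at the critical
    distance), near zero for extended chains.  Uses measured means when both
    distances are present; otherwise interpolates from the fit.
    """
    if profile is not None:
        try:
            return profile.at(d_full) - profile.at(d_crit)
        except KeyError:
            pass
    if fit is not None and fit.converged:
        return float(fit.predict(d_full) - fit.predict(d_crit))
    raise QuantificationError(
        f"d = {d_crit}/{d_full} absent from the profile and no converged fit given"
    )


def infer_folded(
    delta_d50: float,
    rise_ext: float = RISE_EXTENDED,
    rise_helix: float = RISE_HELICAL,
) -> float:
    """Residues folded to a helix that absorb a d50 shift of ``delta_d50``.

    Converting n extended residues (rise_ext Å each) to helical (rise_helix)
    shortens the chain's span by n·(rise_ext − rise_helix) Å, which must be
    made up by delta_d50 extra extended residues: n = rise_ext·Δd50 /
    (rise_ext − rise_helix).
    """
    if not (rise_ext > rise_helix > 0):
        raise ValueError("need rise_ext > rise_helix > 0")
    if delta_d50 < 0:
        warnings.warn("negative d50 shift: compaction cannot be negative; returning 0",
                      stacklevel=2)
        return 0.0
    return rise_ext * delta_d50 / (rise_ext - rise_helix)


def helix_span_residues(
    core_thickness: float = 30.0, rise: float = RISE_HELICAL
) -> tuple[float, int]:
    """Residues needed to span a membrane hydrocarbon core at a given rise.

    Returns (raw, ceiling-rounded).  At the helical rise of 1.5 Å/residue a
    30 Å core takes 20 residues.
    """
    if core_thickness < 0 or rise <= 0:
        raise ValueError("need non-negative thickness and positive rise")
    raw = core_thickness / rise
    return raw, math.ceil(raw)


def compare_conditions(
    profile_a: GlycProfile, profile_b: GlycProfile, d: int, min_n: int = 3
) -> tuple[float, float, str]:
    """Welch two-sample t-test on replicate percent-glycosylation at d.

    Returns (t statistic, p-value, significance stars at 0.01/0.001).
    """
    a = profile_a.replicate_values(d)
    b = profile_b.replicate_values(d)
    if len(a) < min_n or len(b) < min_n:
        raise QuantificationError(
            f"need ≥ {min_n} replicates per condition at d = {d} "
            f"(got {len(a)}, {len(b)})"
        )
    if np.array_equal(np.sort(a), np.sort(b)) and np.std(a) == 0 and np.std(b) == 0:
        return 0.0, 1.0, ""
    t, p = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(t), float(p)
    if math.isnan(t):  # zero variance in both groups, equal means
        return 0.0, 1.0, ""
    stars = "***" if p < 0.001 else "**" if p < 0.01 else ""
    return t, p, stars


def gel_mass_model(
    base_mass_da: float, n_glycans: int, per_glycan_shift_da: float = PER_GLYCAN_SHIFT_KDA * 1000.0
) -> float:
    """Apparent gel mass of a construct carrying 0–2 N-glycans (Da)."""
    if n_glycans not in (0, 1, 2):
        raise ValueError("n_glycans must be 0, 1 or 2")
    return base_mass_da + n_glycans * per_glycan_shift_da


@dataclass
class CompactionCall:
    """Inferred conformational state of a nascent chain from its profile."""

    state: str  # compact | extended | intermediate
    delta_d50: float  # residues, vs the extended reference
    critical_gap: float  # percentage points, G(d_full) − G(d_crit)
    n_folded: float  # residues
    fit: SigmoidFit | None = field(default=None, repr=False)


def call_compaction(
    profile: GlycProfile,
    reference_d50: float = 64.0,
    fit: SigmoidFit | None = None,
    d_crit: int = D_CRITICAL,
    d_full: int = D_FULL,
    compact_shift: float = 3.0,
    compact_gap: float = 25.0,
    extended_shift: float = 1.0,
    extended_gap: float = 10.0,
) -> CompactionCall:
    """Classify a glycosylation profile as compact, extended or intermediate.

    Compact when the d50 shift vs the extended reference is ≥ ``compact_shift``
    residues or the critical-distance gap is ≥ ``compact_gap`` percentage
    points; extended when both the shift ≤ ``extended_shift`` and the gap ≤
    ``extended_gap``; otherwise intermediate.
    """
    if fit is None:
        fit = fit_sigmoid(profile)
    shift = fit.d50 - reference_d50 if fit.converged else float("nan")
    try:
        gap = critical_stat(profile, fit, d_crit=d_crit, d_full=d_full)
    except QuantificationError:
        gap = float("nan")

    shift_ok = not math.isnan(shift)
    gap_ok = not math.isnan(gap)
    if (shift_ok and shift >= compact_shift) or (gap_ok and gap >= compact_gap):
        state = "compact"
    elif (shift_ok and shift <= extended_shift) and (gap_ok and gap <= extended_gap):
        state = "extended"
    elif shift_ok and not gap_ok:
        state = "extended" if shift <= extended_shift else "intermediate"
    else:
        state = "intermediate"

    n_folded = infer_folded(max(shift, 0.0)) if shift_ok else float("nan")
    return CompactionCall(state=state, delta_d50=shift, critical_gap=gap,
                          n_folded=n_folded, fit=fit)
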