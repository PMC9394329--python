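"""The two neuron analyses: paired-condition study and AP-count-grid study.

Analysis A (paired conditions). Per neuron (unit), trials of combined basal
and apical current injections are recorded under two conditions with the
same amplitude grid. Trials are admitted only for amplitude combinations
present — and spiking — under both conditions, so that any within-unit
difference in a PID component cannot be an artifact of differing input
distributions. Admitted trials are cut into fixed windows; per window the
AP count and the mean basal/apical signals are computed; inputs are binned
into equiprobable quantile bins and the AP count into small ordinal
categories, yielding one trivariate distribution per unit and condition.
Within-unit component differences are tested with the exact Wilcoxon
signed-rank test, Bonferroni-corrected.

Analysis B (AP grid). A deterministic spike-count surface over (basal
count, apical count) combinations is turned into trivariate distributions
by placing equal probability on every observed combination in a chosen
range of basal and apical counts. Scanning nested ranges and normalizing
each decomposition by its own joint mutual information reveals how the
unique information asymmetry (UIA) changes sign as basal strength grows,
and supports assessing the four qualitative criteria of cooperative
context-sensitivity (CCS1-CCS4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import TrivariateDistribution
from .info import classical_measures
from .pid import METHODS, PIDResult, decompose, normalize_pid
from .stats import bonferroni, wilcoxon_exact

__all__ = [
    "TrialRecord", "APGrid", "PairedStudy", "CCSThresholds", "CCSAssessment",
    "discretize_trials", "match_conditions", "grid_to_distribution",
    "subset_scan", "detect_uia_bifurcation", "build_paired_study",
    "paired_differences", "paired_tests", "ccs_assess",
    "DEFAULT_OUTPUT_CATEGORIES", "GRID_OUTPUT_CATEGORIES",
]

#: AP-count categories for recorded trials: 0, 1, 2-or-more
DEFAULT_OUTPUT_CATEGORIES: tuple[tuple[int, int | None], ...] = ((0, 0), (1, 1), (2, None))
#: AP-count categories for the grid study: 0, 1-2, 3-4
GRID_OUTPUT_CATEGORIES: tuple[tuple[int, int | None], ...] = ((0, 0), (1, 2), (3, 4))

#: UIA sign tolerance guarding against floating-point sign flips
UIA_SIGN_TOL = 1e-9


@dataclass(frozen=True)
class TrialRecord:
    """One trial: current traces plus AP times for one unit and condition."""

    unit_id: str
    condition: str            #: "control" or "treated"
    basal_amp: float          #: peak basal (somatic) amplitude, pA
    apical_amp: float         #: peak apical (dendritic) amplitude, pA
    basal_trace: np.ndarray   #: pA, sampled every dt_ms
    apical_trace: np.ndarray
    ap_times: np.ndarray      #: ms from trial onset
    dt_ms: float = 1.0

    def __post_init__(self):
        bt = np.asarray(self.basal_trace, dtype=float)
        at = np.asarray(self.apical_trace, dtype=float)
        tt = np.asarray(self.ap_times, dtype=float)
        if bt.shape != at.shape or bt.ndim != 1:
            raise ValueError("basal and apical traces must be 1-d and share length")
        if self.basal_amp < 0 or self.apical_amp < 0:
            raise ValueError("amplitudes must be nonnegative")
        duration = bt.size * self.dt_ms
        if tt.size and (tt.min() < 0 or tt.max() > duration):
            raise ValueError("ap_times outside trace duration")
        object.__setattr__(self, "basal_trace", bt)
        object.__setattr__(self, "apical_trace", at)
        object.__setattr__(self, "ap_times", tt)

    @property
    def duration_ms(self) -> float:
        return self.basal_trace.size * self.dt_ms

    @property
    def n_aps(self) -> int:
        return int(self.ap_times.size)


@dataclass(frozen=True)
class APGrid:
    """Spike counts indexed by (basal input count, apical input count)."""

    basal_levels: tuple[int, ...]
    apical_levels: tuple[int, ...]
    counts: Mapping[tuple[int, int], int]

    def __post_init__(self):
        for (b, a), c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count at ({b}, {a}) is not a nonnegative integer")
            if b not in self.basal_levels or a not in self.apical_levels:
                raise ValueError(f"cell ({b}, {a}) outside the declared levels")

    @property
    def observed(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.counts)

    def count(self, b: int, a: int) -> int:
        return int(self.counts[(b, a)])


# ---------------------------------------------------------------------------
# discretization

def _categorize(count: int, categories: Sequence[tuple[int, int | None]]) -> int:
    for idx, (lo, hi) in enumerate(categories):
        if count >= lo and (hi is None or count <= hi):
            return idx
    raise ValueError(f"AP count {count} matches no output category")


def category_labels(categories: Sequence[tuple[int, int | None]]) -> tuple[str, ...]:
    out = []
    for lo, hi in categories:
        if hi is None:
            out.append(f"{lo}+")
        elif hi == lo:
            out.append(str(lo))
        else:
            out.append(f"{lo}-{hi}")
    return tuple(out)


def quantile_bin(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Equiprobable (quantile) binning; ties on an edge go to the lower bin.

    Returns (bin indices, number of bins actually used). The bin count is
    reduced when fewer distinct values exist than requested bins; a
    constant signal cannot be binned and raises.
    """
    values = np.asarray(values, dtype=float)
    n_distinct = np.unique(values).size
    if n_distinct < 2:
        raise ValueError("input signal is constant; quantile bins are undefined")
    k = min(n_bins, n_distinct)
    edges = np.quantile(values, np.arange(1, k) / k)
    idx = np.searchsorted(edges, values, side="left")
    return idx, k


def discretize_trials(
    trials: Sequence[TrialRecord],
    window_ms: float = 120.0,
    input_bins: int = 4,
    output_categories: Sequence[tuple[int, int | None]] = DEFAULT_OUTPUT_CATEGORIES,
) -> TrivariateDistribution:
    """Empirical trivariate pmf over analysis windows of one unit+condition.

    Every trial is cut into non-overlapping windows of ``window_ms``; per
    window the AP count, mean basal signal and mean apical signal are
    computed. Window means are pooled across trials and quantile-binned.
    """
    if not trials:
        raise ValueError("no trials to discretize")
    b_means, a_means, counts = [], [], []
    for tr in trials:
        samples = int(round(window_ms / tr.dt_ms))
        if samples < 1:
            raise ValueError("window shorter than one sample")
        n_w = tr.basal_trace.size // samples
        if n_w < 1:
            raise ValueError("trace shorter than one full window")
        for w in range(n_w):
            sl = slice(w * samples, (w + 1) * samples)
            t0, t1 = w * window_ms, (w + 1) * window_ms
            b_means.append(tr.basal_trace[sl].mean())
            a_means.append(tr.apical_trace[sl].mean())
            counts.append(int(((tr.ap_times >= t0) & (tr.ap_times < t1)).sum()))
    b_idx, kb = quantile_bin(np.array(b_means), input_bins)
    a_idx, ka = quantile_bin(np.array(a_means), input_bins)
    y_idx = np.array([_categorize(c, output_categories) for c in counts])

    ky = len(output_categories)
    joint = np.zeros((ky, kb, ka))
    np.add.at(joint, (y_idx, b_idx, a_idx), 1.0)
    joint /= joint.sum()
    return TrivariateDistribution(
        alphabet_y=category_labels(output_categories),
        alphabet_b=tuple(range(kb)),
        alphabet_a=tuple(range(ka)),
        pmf=joint,
    )


# ---------------------------------------------------------------------------
# condition matching

def match_conditions(
    trials: Sequence[TrialRecord],
    policy: str = "drop-combination",
) -> tuple[list[TrialRecord], list[TrialRecord], list[tuple[float, float]]]:
    """Admit trials whose (basal, apical) amplitude combination matches.

    A combination is admitted only if it is present under both conditions.
    Under the default ``drop-combination`` policy, a combination that
    evoked zero APs across its trials under either condition is dropped
    from both; under ``drop-trial`` only the individual zero-AP trials are
    dropped (combinations left unmatched as a result are then dropped).

    Returns (control trials, treated trials, matched combinations).
    """
    if policy not in ("drop-combination", "drop-trial"):
        raise ValueError(f"unknown policy {policy!r}")
    by_cond: dict[str, list[TrialRecord]] = {"control": [], "treated": []}
    for tr in trials:
        if tr.condition not in by_cond:
            raise ValueError(f"unexpected condition {tr.condition!r}")
        by_cond[tr.condition].append(tr)

    def combos(sel: Iterable[TrialRecord]) -> set[tuple[float, float]]:
        return {(tr.basal_amp, tr.apical_amp) for tr in sel}

    if policy == "drop-trial":
        kept = {c: [tr for tr in v if tr.n_aps > 0] for c, v in by_cond.items()}
    else:
        dead: set[tuple[float, float]] = set()
        for c, v in by_cond.items():
            aps: dict[tuple[float, float], int] = {}
            for tr in v:
                key = (tr.basal_amp, tr.apical_amp)
                aps[key] = aps.get(key, 0) + tr.n_aps
            dead |= {k for k, n in aps.items() if n == 0}
        kept = {
            c: [tr for tr in v if (tr.basal_amp, tr.apical_amp) not in dead]
            for c, v in by_cond.items()
        }

    admitted = combos(kept["control"]) & combos(kept["treated"])
    if not admitted:
        raise ValueError("no amplitude combination admitted under both conditions")
    control = [tr for tr in kept["control"] if (tr.basal_amp, tr.apical_amp) in admitted]
    treated = [tr for tr in kept["treated"] if (tr.basal_amp, tr.apical_amp) in admitted]
    return control, treated, sorted(admitted)


# ---------------------------------------------------------------------------
# grid study

def grid_to_distribution(
    grid: APGrid,
    basal_range: tuple[int, int],
    apical_range: tuple[int, int],
    output_categories: Sequence[tuple[int, int | None]] = GRID_OUTPUT_CATEGORIES,
) -> TrivariateDistribution:
    """Uniform distribution over the observed grid cells in range.

    Each observed (basal, apical) combination within the ranges receives
    probability 1/n; the basal and apical alphabets are the grid levels in
    range and the output alphabet is the AP-count categories.
    """
    blo, bhi = basal_range
    alo, ahi = apical_range
    bs = tuple(b for b in grid.basal_levels if blo <= b <= bhi)
    as_ = tuple(a for a in grid.apical_levels if alo <= a <= ahi)
    cells = [(b, a) for b in bs for a in as_ if (b, a) in grid.observed]
    if not cells:
        raise ValueError(f"no observed combinations in basal {basal_range} x apical {apical_range}")
    ky = len(output_categories)
    pmf = np.zeros((ky, len(bs), len(as_)))
    ib = {b: i for i, b in enumerate(bs)}
    ia = {a: i for i, a in enumerate(as_)}
    mass = 1.0 / len(cells)
    for (b, a) in cells:
        pmf[_categorize(grid.count(b, a), output_categories), ib[b], ia[a]] += mass
    return TrivariateDistribution(
        alphabet_y=category_labels(output_categories),
        alphabet_b=bs,
        alphabet_a=as_,
        pmf=pmf,
    )


def subset_scan(
    grid: APGrid,
    basal_ranges: Sequence[tuple[int, int]],
    apical_ranges: Sequence[tuple[int, int]],
    methods: Sequence[str] = tuple(METHODS),
    output_categories: Sequence[tuple[int, int | None]] = GRID_OUTPUT_CATEGORIES,
) -> pd.DataFrame:
    """Normalized PIDs for every (basal range, apical range, method).

    Each subset's components are normalized by that subset's joint mutual
    information. Subsets with zero joint mutual information are recorded
    with missing components and a reason, and the scan continues.
    """
    rows = []
    for (alo, ahi) in apical_ranges:
        for (blo, bhi) in basal_ranges:
            base = {
                "basal_lo": blo, "basal_hi": bhi,
                "apical_lo": alo, "apical_hi": ahi,
            }
            try:
                dist = grid_to_distribution(grid, (blo, bhi), (alo, ahi), output_categories)
                s = classical_measures(dist)
                if s.jmi <= 1e-12:
                    raise ZeroDivisionError("zero joint mutual information")
            except (ValueError, ZeroDivisionError) as exc:
                for method in methods:
                    rows.append({**base, "method": method, "unq_b": np.nan,
                                 "unq_a": np.nan, "shd": np.nan, "syn": np.nan,
                                 "jmi": np.nan, "uia": np.nan, "note": str(exc)})
                continue
            for method in methods:
                r = normalize_pid(decompose(dist, method))
                rows.append({**base, "method": method,
                             "unq_b": r.unq_b, "unq_a": r.unq_a,
                             "shd": r.shd, "syn": r.syn, "jmi": s.jmi,
                             "uia": r.unq_b - r.unq_a, "note": ""})
    return pd.DataFrame(rows)


def detect_uia_bifurcation(scan: pd.DataFrame, tol: float = UIA_SIGN_TOL) -> pd.DataFrame:
    """Per apical range, the basal range where the UIA changes sign.

    Basal ranges are ordered by upper endpoint (range strength). Reports
    the first basal upper endpoint at which UIA >= 0 after having been
    negative (column ``switch_basal_hi``), or the constant sign. The UIA is
    method-independent, so one method's rows suffice.
    """
    method = scan["method"].iloc[0]
    sel = scan[(scan["method"] == method) & scan["uia"].notna()]
    out = []
    for (alo, ahi), g in sel.groupby(["apical_lo", "apical_hi"]):
        g = g.sort_values("basal_hi")
        signs = np.where(g["uia"] > tol, 1, np.where(g["uia"] < -tol, -1, 0))
        row = {"apical_lo": alo, "apical_hi": ahi,
               "switch_basal_hi": np.nan, "sign": ""}
        seen_negative = False
        for s_val, bhi in zip(signs, g["basal_hi"]):
            if s_val < 0:
                seen_negative = True
            elif s_val >= 0 and seen_negative:
                row["switch_basal_hi"] = bhi
                row["sign"] = "switch"
                break
        if row["sign"] != "switch":
            uniq = set(signs.tolist())
            row["sign"] = "+" if uniq <= {0, 1} else ("-" if uniq <= {0, -1} else "mixed")
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# paired study

@dataclass(frozen=True)
class PairedStudy:
    """Per-unit distributions and normalized PIDs under both conditions."""

    distributions: Mapping[str, Mapping[str, TrivariateDistribution]]
    pids: Mapping[str, Mapping[str, Mapping[str, PIDResult]]]  #: unit -> condition -> method
    matched_combos: Mapping[str, Sequence[tuple[float, float]]]

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(self.distributions)


def build_paired_study(
    trials: Sequence[TrialRecord],
    methods: Sequence[str] = tuple(METHODS),
    window_ms: float = 120.0,
    input_bins: int = 4,
    output_categories: Sequence[tuple[int, int | None]] = DEFAULT_OUTPUT_CATEGORIES,
    policy: str = "drop-combination",
) -> PairedStudy:
    """Match, discretize and decompose every unit's two conditions."""
    by_unit: dict[str, list[TrialRecord]] = {}
    for tr in trials:
        by_unit.setdefault(tr.unit_id, []).append(tr)
    dists: dict[str, dict[str, TrivariateDistribution]] = {}
    pids: dict[str, dict[str, dict[str, PIDResult]]] = {}
    combos: dict[str, list[tuple[float, float]]] = {}
    for unit, unit_trials in sorted(by_unit.items()):
        control, treated, matched = match_conditions(unit_trials, policy=policy)
        combos[unit] = matched
        dists[unit] = {}
        pids[unit] = {}
        for cond, sel in (("control", control), ("treated", treated)):
            dist = discretize_trials(sel, window_ms, input_bins, output_categories)
            dists[unit][cond] = dist
            pids[unit][cond] = {
                m: normalize_pid(decompose(dist, m)) for m in methods
            }
    return PairedStudy(distributions=dists, pids=pids, matched_combos=combos)


COMPONENTS = ("unq_b", "unq_a", "shd", "syn")


def paired_differences(study: PairedStudy, method: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-unit differences (treated - control) of normalized components.

    Returns (per-unit differences, summary) where the summary holds the
    sample median and quartiles per component.
    """
    rows = []
    for unit in study.units:
        conds = study.pids[unit]
        if "control" not in conds or "treated" not in conds:
            raise ValueError(f"unit {unit} lacks a condition")
        rec: dict[str, float | str] = {"unit": unit}
        for comp in COMPONENTS:
            rec[comp] = getattr(conds["treated"][method], comp) - getattr(
                conds["control"][method], comp
            )
        rec["uia"] = (rec["unq_b"] - rec["unq_a"])
        rows.append(rec)
    diffs = pd.DataFrame(rows).set_index("unit")
    summary = pd.DataFrame({
        "median": diffs.median(),
        "q_lower": diffs.quantile(0.25),
        "q_upper": diffs.quantile(0.75),
    })
    return diffs, summary


def paired_tests(
    study: PairedStudy,
    methods: Sequence[str] = tuple(METHODS),
    components: Sequence[str] = COMPONENTS,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Exact Wilcoxon tests of zero median difference, Bonferroni-corrected.

    ``m_tests`` defaults to the number of tests performed here; the
    correction is min(m P, 1).
    """
    rows = []
    for method in methods:
        diffs, _ = paired_differences(study, method)
        for comp in components:
            d = diffs[comp].to_numpy()
            rows.append({
                "method": method, "component": comp,
                "median_diff": float(np.median(d)),
                "p_raw": wilcoxon_exact(d),
            })
    df = pd.DataFrame(rows)
    m = m_tests if m_tests is not None else len(df)
    df["p_corrected"] = bonferroni(df["p_raw"].to_numpy(), m)
    return df


# ---------------------------------------------------------------------------
# cooperative context-sensitivity

@dataclass(frozen=True)
class CCSThresholds:
    """Thresholds making the qualitative CCS criteria reproducible.

    Fractions of the joint mutual information: the drive's unique share
    must reach ``drive``, the context's unique share must stay within
    ``ctx`` in magnitude, and shared-plus-synergy must reach ``joint``.
    """

    drive: float = 0.20
    ctx: float = 0.05
    joint: float = 0.10
    monotone_tol: float = 0.02


@dataclass(frozen=True)
class CCSAssessment:
    ccs1: bool
    ccs2: bool
    ccs3: bool
    ccs4: bool
    thresholds: CCSThresholds
    evidence: dict = field(repr=False)


def ccs_assess(
    scan: pd.DataFrame,
    grid: APGrid,
    thresholds: CCSThresholds = CCSThresholds(),
) -> CCSAssessment:
    """Assess the four cooperative-context-sensitivity properties.

    CCS1 (drive sufficient): the output varies with basal input in the
    absence of apical input. CCS2 (drive necessary): no APs at zero basal
    input. CCS3: some scanned subset transmits unique drive information
    with negligible unique context (mis)information alongside shared or
    synergistic structure. CCS4: as basal strength rises through the weak
    regime total transmission about the drive grows, and shared/synergy
    shrink beyond it.
    """
    apical0 = [grid.count(b, 0) for b in grid.basal_levels if (b, 0) in grid.observed]
    basal0 = [grid.count(0, a) for a in grid.apical_levels if (0, a) in grid.observed]
    if not apical0 or not basal0:
        raise ValueError("grid lacks the zero-apical or zero-basal slice")
    ccs1 = len(set(apical0)) > 1
    ccs2 = all(c == 0 for c in basal0)

    ok = scan[scan["uia"].notna()].copy()
    ok["ccs3"] = (
        (ok["unq_b"] >= thresholds.drive)
        & (ok["unq_a"].abs() <= thresholds.ctx)
        & ((ok["shd"] + ok["syn"]) >= thresholds.joint)
    )
    ccs3 = bool(ok["ccs3"].any())

    # weak regime: basal ranges whose upper end is below the basal-alone
    # firing threshold of the grid
    fire_alone = [b for b in grid.basal_levels
                  if (b, 0) in grid.observed and grid.count(b, 0) > 0]
    threshold_alone = min(fire_alone) if fire_alone else max(grid.basal_levels)
    ccs4_rows = []
    for (method, alo, ahi), g in ok.groupby(["method", "apical_lo", "apical_hi"]):
        g = g.sort_values("basal_hi")
        if len(g) < 3:
            continue
        total_b = (g["unq_b"] + g["shd"] + g["syn"]).to_numpy()
        shd = g["shd"].to_numpy()
        syn = g["syn"].to_numpy()
        bhi = g["basal_hi"].to_numpy()
        weak = bhi <= threshold_alone
        if weak.sum() < 2 or (~weak).sum() < 1:
            continue
        k = int(np.nonzero(weak)[0][-1])
        grows = total_b[k] > total_b[0] - thresholds.monotone_tol
        shrinks = (shd[-1] <= shd[k] + thresholds.monotone_tol) and (
            syn[-1] <= syn[k] + thresholds.monotone_tol
        )
        ccs4_rows.append({"method": method, "apical_lo": alo, "apical_hi": ahi,
                          "grows_weak": grows, "shrinks_after": shrinks,
                          "ccs4": grows and shrinks})
    ccs4_df = pd.DataFrame(ccs4_rows)
    ccs4 = bool(len(ccs4_df) and ccs4_df["ccs4"].any())

    return CCSAssessment(
        ccs1=ccs1, ccs2=ccs2, ccs3=ccs3, ccs4=ccs4, thresholds=thresholds,
        evidence={
            "apical_absent_counts": apical0,
            "basal_absent_counts": basal0,
            "ccs3_rows": ok,
            "ccs4_rows": ccs4_df,
            "basal_threshold_alone": threshold_alone,
        },
    )
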