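"""Non-parametric cohort statistics for rare-event enumeration tables.

The comparison battery mirrors standard liquid-biopsy practice: Mann-Whitney U
(Wilcoxon rank-sum) for unpaired cohort contrasts (e.g. cancer vs normal
donors), Wilcoxon signed-rank for draws matched within a patient (site or
timepoint pairs), and Spearman rank correlation for continuous/ordinal
clinical covariates.  Two-sided tests decide significance at alpha (strict
``<``); for significant results one-sided tests are then run solely to label
the direction of the effect.

Exact small-sample null distributions are computed by dynamic programming
over (doubled) midranks, which handles ties, and agree with brute-force
enumeration of all group assignments / sign patterns.  Large samples use the
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonSpec",
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "spearman_correlation",
    "directional_followup",
    "run_comparisons",
    "correlate_clinical",
    "default_comparison_specs",
]

#: sample-size ceiling (n_x + n_y) for the exact Mann-Whitney null in auto
#: mode; the rank-sum convolution is cheap well beyond the smallest samples
EXACT_MWU_MAX_N = 20
#: sample-size ceiling (non-zero pairs) for the exact signed-rank null
EXACT_WILCOXON_MAX_N = 20
#: sample-size ceiling for the exact Spearman permutation null
EXACT_SPEARMAN_MAX_N = 7


# ---------------------------------------------------------------------------
# exact null distributions (dynamic programming over doubled midranks)
# ---------------------------------------------------------------------------

def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so tied ranks stay integral."""
    r = 2.0 * sps.rankdata(values)
    ri = np.rint(r).astype(np.int64)
    if not np.allclose(r, ri):  # pragma: no cover - midranks are half-integral
        raise AssertionError("midranks are not half-integral")
    return ri


def _ranksum_null(ranks2: Sequence[int], n_select: int) -> dict[int, int]:
    """Distribution of the (doubled) rank sum over all subsets of size n_select.

    dist[s] = number of ``n_select``-subsets of ``ranks2`` with sum s.
    """
    # dp[k] maps rank-sum -> count for subsets of size k
    dp: list[dict[int, int]] = [dict() for _ in range(n_select + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(n_select, len(ranks2)) - 1, -1, -1):
            if not dp[k]:
                continue
            target = dp[k + 1]
            for s, c in dp[k].items():
                target[s + r] = target.get(s + r, 0) + c
    return dp[n_select]


def _signedrank_null(ranks2: Sequence[int]) -> dict[int, int]:
    """Distribution of the (doubled) positive-rank sum over all 2^n sign patterns."""
    dist = {0: 1}
    for r in ranks2:
        new: dict[int, int] = {}
        for s, c in dist.items():
            new[s] = new.get(s, 0) + c        # negative sign: rank not added
            new[s + r] = new.get(s + r, 0) + c
        dist = new
    return dist


def _tail_probs(dist: Mapping[int, int], observed: int) -> tuple[float, float]:
    """(P(S <= observed), P(S >= observed)) under the discrete null."""
    total = sum(dist.values())
    le = sum(c for s, c in dist.items() if s <= observed)
    ge = sum(c for s, c in dist.items() if s >= observed)
    return le / total, ge / total


def _two_sided_from_tails(p_le: float, p_ge: float) -> float:
    """Double the smaller tail, capped at 1."""
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    Returns ``(U, p_two_sided)`` where U counts (x > y) pairs with ties as
    half.  Exact mode enumerates the permutation null of the rank sum
    (tie-aware); approx mode uses the normal approximation with tie and
    continuity corrections.  The two-sided p doubles the smaller tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0

    if mode == "auto":
        mode = "exact" if n_x + n_y <= EXACT_MWU_MAX_N else "approx"

    if mode == "exact":
        ranks2 = _doubled_midranks(pooled)
        dist = _ranksum_null(list(ranks2), n_x)
        obs = int(np.rint(2.0 * r_x))
        p_le, p_ge = _tail_probs(dist, obs)
        return u_x, _two_sided_from_tails(p_le, p_ge)

    mean_u = n_x * n_y / 2.0
    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u_x, 1.0  # all observations tied
    z = (u_x - mean_u - 0.5 * np.sign(u_x - mean_u)) / np.sqrt(var_u)
    return u_x, min(1.0, 2.0 * float(sps.norm.sf(abs(z))))


def _mwu_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: Literal["greater", "less"],
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> float:
    """One-sided Mann-Whitney p for x stochastically greater (or less) than y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0
    if mode == "auto":
        mode = "exact" if n_x + n_y <= EXACT_MWU_MAX_N else "approx"
    if mode == "exact":
        dist = _ranksum_null(list(_doubled_midranks(pooled)), n_x)
        p_le, p_ge = _tail_probs(dist, int(np.rint(2.0 * r_x)))
        return p_ge if alternative == "greater" else p_le
    mean_u = n_x * n_y / 2.0
    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return 1.0
    if alternative == "greater":
        z = (u_x - mean_u - 0.5) / np.sqrt(var_u)
        return float(sps.norm.sf(z))
    z = (u_x - mean_u + 0.5) / np.sqrt(var_u)
    return float(sps.norm.cdf(z))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    diffs: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
    zero_method: Literal["drop", "pratt"] = "drop",
) -> tuple[float, float, bool]:
    """Wilcoxon signed-rank test on paired differences.

    Returns ``(W_plus, p_two_sided, degenerate)``.  Zero differences are
    dropped by default (classical convention; ``zero_method='pratt'`` keeps
    them in the ranking but never in W+).  If every difference is zero the
    result is the degenerate ``(0.0, 1.0, True)``.  Exact mode enumerates all
    2^n sign patterns (via convolution); ties receive midranks.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one paired difference")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return 0.0, 1.0, True

    if zero_method == "drop":
        ranks = sps.rankdata(np.abs(nonzero))
        signs = np.sign(nonzero)
    else:  # pratt: rank |d| including zeros, then discard zero ranks
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        signs = np.sign(d[keep])
    n = ranks.size
    w_plus = float(ranks[signs > 0].sum())

    if mode == "auto":
        mode = "exact" if n <= EXACT_WILCOXON_MAX_N else "approx"

    if mode == "exact":
        ranks2 = np.rint(2.0 * ranks).astype(np.int64)
        dist = _signedrank_null(list(ranks2))
        obs = int(np.rint(2.0 * w_plus))
        p_le, p_ge = _tail_probs(dist, obs)
        return w_plus, _two_sided_from_tails(p_le, p_ge), False

    mean_w = ranks.sum() / 2.0
    var_w = float((ranks**2).sum()) / 4.0
    if var_w <= 0:
        return w_plus, 1.0, True
    z = (w_plus - mean_w - 0.5 * np.sign(w_plus - mean_w)) / np.sqrt(var_w)
    return w_plus, min(1.0, 2.0 * float(sps.norm.sf(abs(z)))), False


def _wilcoxon_one_sided(
    diffs: Sequence[float], alternative: Literal["greater", "less"],
    mode: Literal["auto", "exact", "approx"] = "auto",
    zero_method: Literal["drop", "pratt"] = "drop",
) -> float:
    """One-sided signed-rank p for the differences tending positive ('greater')."""
    d = np.asarray(diffs, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return 1.0
    if zero_method == "drop":
        ranks = sps.rankdata(np.abs(nonzero))
        signs = np.sign(nonzero)
    else:
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        signs = np.sign(d[keep])
    n = ranks.size
    w_plus = float(ranks[signs > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= EXACT_WILCOXON_MAX_N else "approx"
    if mode == "exact":
        dist = _signedrank_null(list(np.rint(2.0 * ranks).astype(np.int64)))
        p_le, p_ge = _tail_probs(dist, int(np.rint(2.0 * w_plus)))
        return p_ge if alternative == "greater" else p_le
    mean_w = ranks.sum() / 2.0
    var_w = float((ranks**2).sum()) / 4.0
    if var_w <= 0:
        return 1.0
    if alternative == "greater":
        return float(sps.norm.sf((w_plus - mean_w - 0.5) / np.sqrt(var_w)))
    return float(sps.norm.cdf((w_plus - mean_w + 0.5) / np.sqrt(var_w)))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman_correlation(
    x: Sequence[float], y: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> tuple[float, float]:
    """Spearman rank correlation ``(rho, p_two_sided)``.

    rho is the Pearson correlation of midranks.  The p-value uses the
    t-approximation, or exact permutation enumeration for n <= 7.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant input: rank variance is zero")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if mode == "auto":
        mode = "exact" if n <= EXACT_SPEARMAN_MAX_N else "approx"

    if mode == "exact":
        # permutation null of |rho| over all n! orderings of y
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        rx_c = rx - rx.mean()
        denom_x = np.sqrt((rx_c**2).sum())
        for perm in itertools.permutations(range(n)):
            ry_p = ry[list(perm)]
            ry_c = ry_p - ry_p.mean()
            r = float((rx_c * ry_c).sum() / (denom_x * np.sqrt((ry_c**2).sum())))
            total += 1
            if abs(r) >= target:
                count += 1
        return rho, count / total

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, min(1.0, 2.0 * float(sps.t.sf(abs(t), df=n - 2)))


# ---------------------------------------------------------------------------
# comparison battery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonSpec:
    """One cohort contrast for one analyte.

    unpaired: ``group_col`` (e.g. cohort) split into ``levels`` (a, b) after
    applying ``filters``; Mann-Whitney U.
    paired: ``group_col`` (timepoint or site) levels (a, b), matched within
    patient after ``filters``; signed-rank on per-patient (b - a) differences.
    Direction 'increase' means level b tends larger than level a.
    """

    analyte: str
    kind: Literal["unpaired", "paired"]
    group_col: str
    levels: tuple[str, str]
    filters: Mapping[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def label(self) -> str:
        filt = ",".join(f"{k}={v}" for k, v in sorted(self.filters.items()))
        base = f"{self.group_col}:{self.levels[0]}-vs-{self.levels[1]}"
        return f"{base}({filt})" if filt else base


@dataclass
class TestResult:
    """One statistical comparison row."""

    __test__ = False  # not a pytest class despite the name

    analyte: str
    comparison: str
    method: str
    n: int
    statistic: float
    p_two_sided: float
    direction: Literal["increase", "decrease", "none"] = "none"
    p_one_sided: float | None = None
    note: str = ""


def directional_followup(
    result: TestResult,
    p_greater: float,
    p_less: float,
    alpha: float = 0.05,
) -> TestResult:
    """Apply the two-sided -> one-sided follow-up rule.

    Only when the two-sided p is significant (strictly below alpha) are the
    one-sided tests consulted; the direction is the smaller one-sided tail
    ('increase' when the b-side / second group tends larger).  Otherwise the
    direction stays 'none' and no one-sided p is reported.
    """
    if result.p_two_sided < alpha:
        if p_greater <= p_less:
            result.direction = "increase"
            result.p_one_sided = p_greater
        else:
            result.direction = "decrease"
            result.p_one_sided = p_less
    else:
        result.direction = "none"
        result.p_one_sided = None
    return result


def _apply_filters(df: pd.DataFrame, filters: Mapping[str, str]) -> pd.DataFrame:
    for col, val in filters.items():
        df = df[df[col] == val]
    return df


def run_comparisons(
    enum_wide: pd.DataFrame,
    samples: pd.DataFrame,
    specs: Iterable[ComparisonSpec],
    mode: Literal["auto", "exact", "approx"] = "auto",
    add_bh: bool = False,
) -> pd.DataFrame:
    """Run a battery of comparisons against a wide enumeration table.

    ``enum_wide`` is indexed by sample_id with one column per analyte
    (events/mL); ``samples`` carries sample_id, patient_id, cohort, site,
    timepoint.  Paired specs match the two draws within each patient and
    silently exclude patients missing either member; results with fewer than
    two usable observations are flagged 'insufficient' rather than dropped.
    """
    meta = samples.set_index("sample_id")
    rows: list[TestResult] = []
    for spec in sorted(specs, key=lambda s: (s.analyte, s.label)):
        sub = _apply_filters(meta, spec.filters)
        if spec.analyte not in enum_wide.columns:
            raise KeyError(f"analyte {spec.analyte!r} not in enumeration table")
        values = enum_wide[spec.analyte]
        a_level, b_level = spec.levels
        if spec.kind == "unpaired":
            ids_a = sub.index[sub[spec.group_col] == a_level]
            ids_b = sub.index[sub[spec.group_col] == b_level]
            x = values.reindex(ids_a).dropna().to_numpy()
            y = values.reindex(ids_b).dropna().to_numpy()
            res = TestResult(spec.analyte, spec.label, "mann-whitney-u",
                             int(x.size + y.size), np.nan, 1.0)
            if x.size < 1 or y.size < 1 or x.size + y.size < 2:
                res.note = "insufficient"
                rows.append(res)
                continue
            u, p2 = mann_whitney_u(x, y, mode=mode)
            res.statistic, res.p_two_sided = u, p2
            # direction: does level b exceed level a?
            p_b_greater = _mwu_one_sided(y, x, "greater", mode=mode)
            p_b_less = _mwu_one_sided(y, x, "less", mode=mode)
            rows.append(directional_followup(res, p_b_greater, p_b_less, spec.alpha))
        else:
            sub_a = sub[sub[spec.group_col] == a_level]
            sub_b = sub[sub[spec.group_col] == b_level]
            merged = pd.merge(
                sub_a.reset_index()[["sample_id", "patient_id"]],
                sub_b.reset_index()[["sample_id", "patient_id"]],
                on="patient_id", suffixes=("_a", "_b"),
            ).sort_values("patient_id")
            va = values.reindex(merged["sample_id_a"]).to_numpy()
            vb = values.reindex(merged["sample_id_b"]).to_numpy()
            ok = np.isfinite(va) & np.isfinite(vb)
            diffs = (vb - va)[ok]
            res = TestResult(spec.analyte, spec.label, "wilcoxon-signed-rank",
                             int(diffs.size), np.nan, 1.0)
            if diffs.size < 2:
                res.note = "insufficient"
                rows.append(res)
                continue
            w, p2, degenerate = wilcoxon_signed_rank(diffs, mode=mode)
            res.statistic, res.p_two_sided = w, p2
            if degenerate:
                res.note = "degenerate"
                rows.append(res)
                continue
            p_gr = _wilcoxon_one_sided(diffs, "greater", mode=mode)
            p_ls = _wilcoxon_one_sided(diffs, "less", mode=mode)
            rows.append(directional_followup(res, p_gr, p_ls, spec.alpha))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if add_bh and len(out):
        usable = out["note"] != "insufficient"
        adj = np.full(len(out), np.nan)
        if usable.any():
            adj[usable.to_numpy()] = multipletests(
                out.loc[usable, "p_two_sided"], method="fdr_bh")[1]
        out["p_bh"] = adj
    return out.reset_index(drop=True)


def default_comparison_specs(
    samples: pd.DataFrame, analytes: Sequence[str], alpha: float = 0.05
) -> list[ComparisonSpec]:
    """Build the standard contrast battery present in the sample table.

    Per analyte: PDAC-vs-ND unpaired at each (site, timepoint) with ND data;
    paired timepoint contrasts within each site; paired PB-vs-PoVB contrasts
    within each timepoint (PDAC only).
    """
    specs: list[ComparisonSpec] = []
    pdac = samples[samples["cohort"] == "PDAC"]
    has_nd = (samples["cohort"] == "ND").any()
    sites = sorted(pdac["site"].unique())
    order = {"Pre": 0, "During": 1, "Post": 2}
    for analyte in analytes:
        if has_nd:
            specs.append(ComparisonSpec(
                analyte, "unpaired", "cohort", ("ND", "PDAC"),
                {"site": "PB", "timepoint": "Pre"}, alpha))
        for site in sites:
            tps = sorted(pdac.loc[pdac["site"] == site, "timepoint"].unique(),
                         key=lambda t: order[t])
            for a, b in itertools.combinations(tps, 2):
                specs.append(ComparisonSpec(
                    analyte, "paired", "timepoint", (a, b),
                    {"cohort": "PDAC", "site": site}, alpha))
        for tp in sorted(pdac["timepoint"].unique(), key=lambda t: order[t]):
            at_tp = pdac[pdac["timepoint"] == tp]
            if {"PB", "PoVB"} <= set(at_tp["site"].unique()):
                specs.append(ComparisonSpec(
                    analyte, "paired", "site", ("PB", "PoVB"),
                    {"cohort": "PDAC", "timepoint": tp}, alpha))
    return specs


# ---------------------------------------------------------------------------
# clinical correlations
# ---------------------------------------------------------------------------

def correlate_clinical(
    enum_wide: pd.DataFrame,
    clinical: pd.DataFrame,
    variable_kinds: Mapping[str, str],
    analytes: Sequence[str] | None = None,
    ordinal_codes: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Correlate analyte levels (one row per patient) with clinical variables.

    ``enum_wide`` must be indexed by patient_id here (pre-surgery draws).
    Binary categorical variables use the rank-sum test with the signed
    standardised z as the statistic (positive when the second sorted level
    has larger analyte values); continuous and ordinal variables use Spearman
    rho.  Missing values are dropped pairwise.
    """
    ordinal_codes = ordinal_codes or {}
    analytes = list(analytes) if analytes is not None else list(enum_wide.columns)
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    rows = []
    for var, kind in variable_kinds.items():
        if var not in clin.columns:
            raise KeyError(f"clinical variable {var!r} missing")
        col = clin[var]
        for analyte in analytes:
            joined = pd.concat([col, enum_wide[analyte]], axis=1, join="inner").dropna()
            v, a = joined.iloc[:, 0], joined.iloc[:, 1].astype(float)
            if kind == "categorical":
                levels = sorted(v.unique())
                if len(levels) != 2:
                    raise ValueError(
                        f"categorical variable {var!r} must be binary, has {levels}")
                ref, alt = levels
                x = a[v == alt].to_numpy()
                y = a[v == ref].to_numpy()
                if x.size < 1 or y.size < 1:
                    continue
                # signed z from the normal approximation of the rank-sum
                pooled = np.concatenate([x, y])
                ranks = sps.rankdata(pooled)
                u = float(ranks[: x.size].sum()) - x.size * (x.size + 1) / 2.0
                mean_u = x.size * y.size / 2.0
                n = x.size + y.size
                _, tc = np.unique(pooled, return_counts=True)
                tie_term = float(((tc**3) - tc).sum())
                var_u = x.size * y.size / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
                if var_u <= 0:
                    continue
                z = (u - mean_u) / np.sqrt(var_u)
                p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
                rows.append({"variable": var, "variable_kind": kind,
                             "analyte": analyte, "method": "rank-sum-z",
                             "statistic": z, "p": p,
                             "reference_level": str(ref)})
            else:
                if kind == "ordinal" and var in ordinal_codes:
                    v = v.map(ordinal_codes[var])
                vv = pd.to_numeric(v, errors="coerce")
                mask = vv.notna()
                if mask.sum() < 3:
                    continue
                try:
                    rho, p = spearman_correlation(vv[mask].to_numpy(),
                                                  a[mask].to_numpy())
                except ValueError:
                    continue  # constant variable carries no rank information
                rows.append({"variable": var, "variable_kind": kind,
                             "analyte": analyte, "method": "spearman",
                             "statistic": rho, "p": p, "reference_level": ""})
    return pd.DataFrame(rows)


#: documented ordinal codings for pathological stage variables
PT_STAGE_CODES = {"pT0": 0, "pT1": 1, "pT2": 2, "pT3": 3, "pT4": 4}
PN_STAGE_CODES = {"pN0": 0, "pN1": 1}
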