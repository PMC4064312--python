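"""Copy-number analysis from exon coverage log-ratios.

The tumor specimen is modelled as a two-component cellular mixture: a
fraction ``p`` (purity) of tumor cells carrying integer copy number ``C`` at
a locus, and ``1 - p`` normal cells carrying 2 copies.  Against a
process-matched normal, the expected coverage log-ratio of a segment is

    E[lr] = log2[ (p*C + 2(1-p)) / (p*ploidy + 2(1-p)) ]

where ``ploidy`` is the tumor's average copy number (the normalisation
state of the whole profile).  Heterozygous-SNP allele fractions carry the
complementary allelic signal,

    E[BAF] = (p*m + (1-p)) / (p*C + 2(1-p))

with ``m`` the minor-allele copy number; jointly they resolve the
purity/ploidy degeneracy that log-ratios alone leave open (halving purity
while mapping C -> 2C - 2 leaves every log-ratio unchanged, but moves the
BAF of any odd-copy or LOH segment).

Calling rule: focal amplification at segments with >= 6 copies, homozygous
deletion at 0 copies, emitted only for samples with purity > 20%.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LogRatioProfile", "Segment", "CnaCall", "expected_logratio",
    "expected_baf", "compute_logratios", "segment_profile",
    "fit_purity_ploidy", "call_focal_cnas", "PurityPloidyModel",
    "PurityPloidyResults",
]

LR_FLOOR = -8.0  # log2 floor standing in for -inf at C=0, p=1
AMPLIFICATION_COPIES = 6
DELETION_COPIES = 0
PURITY_GATE = 0.20


@dataclass
class LogRatioProfile:
    """Ordered per-exon log2 tumor/normal coverage ratios."""

    lr: np.ndarray
    exons: pd.DataFrame | None = None  # contig, start, end, gene (optional)

    def __post_init__(self) -> None:
        self.lr = np.asarray(self.lr, dtype=float)
        if not np.isfinite(self.lr).all():
            raise ValueError("log-ratio profile contains non-finite values")
        if self.exons is not None and len(self.exons) != self.lr.size:
            raise ValueError("exon table and log-ratio vector lengths differ")

    def __len__(self) -> int:
        return int(self.lr.size)


@dataclass
class Segment:
    start: int  # exon index, inclusive
    end: int  # exon index, exclusive
    mean: float
    n_exons: int
    copies: int | None = None

    @property
    def exon_range(self) -> range:
        return range(self.start, self.end)


@dataclass
class CnaCall:
    gene: str
    kind: str  # amplification | homozygous_deletion
    copies: int
    segment: int  # index into the fitted segment list


def expected_logratio(copies, purity, ploidy, floor: float = LR_FLOOR):
    """Mixture-model expectation of the segment log2 ratio (vectorised)."""
    c = np.asarray(copies, dtype=float)
    p = float(purity)
    if not (0 < p <= 1):
        raise ValueError("purity must be in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    num = p * c + 2.0 * (1.0 - p)
    den = p * float(ploidy) + 2.0 * (1.0 - p)
    with np.errstate(divide="ignore"):
        lr = np.log2(num / den)
    lr = np.maximum(lr, floor)
    return float(lr) if np.isscalar(copies) else lr


def expected_baf(copies, minor, purity):
    """Expected minor-allele fraction at a heterozygous SNP (vectorised)."""
    c = np.asarray(copies, dtype=float)
    m = np.asarray(minor, dtype=float)
    if (m > c).any():
        raise ValueError("minor copies cannot exceed total copies")
    p = float(purity)
    out = (p * m + (1.0 - p)) / (p * c + 2.0 * (1.0 - p))
    return float(out) if np.isscalar(copies) and np.isscalar(minor) else out


def compute_logratios(
    tumor_coverage: pd.DataFrame,
    normal_coverage: pd.DataFrame,
    min_normal: float = 10.0,
    log: list | None = None,
) -> LogRatioProfile:
    """log2(tumor/normal) per exon, median-centred to zero.

    Inputs are DataFrames keyed by (contig, start, end) with a ``coverage``
    column.  Exons whose normal coverage falls below ``min_normal`` are
    dropped (and logged): the ratio there is dominated by the denominator's
    sampling noise.
    """
    key = ["contig", "start", "end"]
    t = tumor_coverage.set_index(key)["coverage"]
    n = normal_coverage.set_index(key)["coverage"]
    common = t.index.intersection(n.index)
    if len(common) == 0:
        raise ValueError("tumor and normal coverage share no exons")
    t, n = t.loc[common], n.loc[common]
    keep = n >= min_normal
    if log is not None:
        for idx in common[~keep]:
            log.append(f"exon {idx} dropped: normal coverage below {min_normal}")
    t, n = t[keep], n[keep]
    lr = np.log2(t.to_numpy(dtype=float) / n.to_numpy(dtype=float))
    lr = lr - np.median(lr)
    exons = pd.DataFrame(list(t.index), columns=key)
    if "gene" in tumor_coverage.columns:
        gene_map = tumor_coverage.set_index(key)["gene"]
        exons["gene"] = gene_map.loc[t.index].to_numpy()
    order = exons.sort_values(key).index
    return LogRatioProfile(lr=lr[order], exons=exons.loc[order].reset_index(drop=True))


def _sse(csum, csum2, i, j):
    """Sum of squared deviations of lr[i:j] around its mean, O(1)."""
    n = j - i
    s = csum[j] - csum[i]
    return (csum2[j] - csum2[i]) - s * s / n


def segment_profile(profile: LogRatioProfile | np.ndarray,
                    penalty: float | None = None) -> list[Segment]:
    """Penalised least-squares binary segmentation on exon order.

    A split is accepted while the best single changepoint reduces the sum of
    squared residuals by more than ``penalty``.  The default penalty scales
    as ``3 * sigma^2 * log(n)`` with sigma estimated robustly from first
    differences, which leaves a flat noisy profile (sd 0.1, thousands of
    exons) un-split while any copy-level step over a handful of exons is
    detected.
    """
    lr = profile.lr if isinstance(profile, LogRatioProfile) else np.asarray(profile, float)
    n = lr.size
    if n < 2:
        return [Segment(0, n, float(lr.mean()) if n else 0.0, n)]
    if penalty is None:
        diffs = np.diff(lr)
        sigma = np.median(np.abs(diffs)) / (np.sqrt(2.0) * 0.674489751) if n > 2 else 0.0
        sigma = max(sigma, 1e-6)
        penalty = 3.0 * sigma * sigma * np.log(n)

    csum = np.concatenate([[0.0], np.cumsum(lr)])
    csum2 = np.concatenate([[0.0], np.cumsum(lr * lr)])
    breakpoints: list[int] = []

    def recurse(i: int, j: int) -> None:
        if j - i < 2:
            return
        base = _sse(csum, csum2, i, j)
        ks = np.arange(i + 1, j)
        left_n = ks - i
        right_n = j - ks
        ls = csum[ks] - csum[i]
        rs = csum[j] - csum[ks]
        sse_split = (
            (csum2[ks] - csum2[i]) - ls * ls / left_n
            + (csum2[j] - csum2[ks]) - rs * rs / right_n
        )
        k = int(ks[np.argmin(sse_split)])
        if base - sse_split[k - i - 1] > penalty:
            breakpoints.append(k)
            recurse(i, k)
            recurse(k, j)

    recurse(0, n)
    bounds = [0] + sorted(breakpoints) + [n]
    return [
        Segment(a, b, float(lr[a:b].mean()), b - a)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


class PurityPloidyModel:
    """Joint grid-search fit of purity, tumor ploidy and segment copy numbers.

    For each candidate (purity, ploidy) on the grid, every segment is
    assigned the integer copy number (and, when SNP allele fractions overlap
    it, the minor-copy count) minimising the Gaussian residual of its mean
    log-ratio (and BAFs) against the mixture-model expectations; the
    candidate maximising the summed log-likelihood wins.  Ties break toward
    lower ploidy, then higher purity, which resolves the halving degeneracy
    deterministically.

    Parameters
    ----------
    segments : list of Segment
    bafs : DataFrame with columns ``segment`` (index into segments) and
        ``baf``, or None
    lr_sd : per-exon log-ratio noise sd; estimated from within-segment
        spread when None
    baf_sd : per-SNP allele-fraction noise sd
    baf_weight : relative weight of the BAF term (1.0 = equal weight)
    """

    def __init__(self, segments, bafs=None, purity_grid=None, ploidy_grid=None,
                 lr_sd=None, baf_sd=0.05, baf_weight=1.0, max_copies=12,
                 tie_margin=3.0, profile: LogRatioProfile | None = None):
        self.segments = list(segments)
        self.bafs = bafs
        self.profile = profile
        self.purity_grid = (np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 10)
                            if purity_grid is None else np.asarray(purity_grid, float))
        self.ploidy_grid = (np.round(np.arange(1.2, 6.0 + 1e-9, 0.05), 10)
                            if ploidy_grid is None else np.asarray(ploidy_grid, float))
        if self.purity_grid.size == 0 or self.ploidy_grid.size == 0:
            raise ValueError("empty purity/ploidy grid")
        if (self.purity_grid <= 0).any() or (self.purity_grid > 1).any():
            raise ValueError("purity grid must lie in (0, 1]")
        self.lr_sd = lr_sd
        self.baf_sd = baf_sd
        self.baf_weight = baf_weight
        self.max_copies = max_copies
        self.tie_margin = tie_margin

    @classmethod
    def from_profile(cls, profile: LogRatioProfile, bafs=None, penalty=None, **kw):
        segs = segment_profile(profile, penalty=penalty)
        if bafs is not None and "segment" not in bafs.columns and "exon" in bafs.columns:
            seg_of_exon = np.empty(len(profile), dtype=int)
            for si, s in enumerate(segs):
                seg_of_exon[s.start:s.end] = si
            bafs = bafs.assign(segment=seg_of_exon[bafs["exon"].to_numpy()])
        return cls(segs, bafs=bafs, profile=profile, **kw)

    def _estimate_lr_sd(self) -> float:
        if self.lr_sd is not None:
            return float(self.lr_sd)
        if self.profile is not None and len(self.segments) >= 1:
            resid = []
            for s in self.segments:
                resid.extend(self.profile.lr[s.start:s.end] - s.mean)
            sd = float(np.std(resid)) if len(resid) > 1 else 0.0
            return max(sd, 0.02)
        return 0.1

    def fit(self) -> "PurityPloidyResults":
        segs = self.segments
        P, T = self.purity_grid, self.ploidy_grid
        sd = self._estimate_lr_sd()
        loglik, copies_by_cand = self._grid_loglik(P, T, sd)

        # The likelihood surface carries near-exact ridges: halving purity
        # while rescaling every segment's copies (genome-doubling family),
        # or shifting all copies by two at doubled ploidy, leaves the
        # log-ratio and BAF expectations (almost) unchanged.  Candidates
        # within ``tie_margin`` log-likelihood units of the optimum are
        # treated as one equivalence set and resolved toward the lower
        # integer ploidy band, then higher purity, then likelihood; the
        # winner is finally walked down the doubling ridge (ploidy/2,
        # purity 2p/(1+p)) while the halved representative stays within the
        # margin.  This picks the parsimonious member of each ridge without
        # ever preferring a materially worse fit.
        best = np.max(loglik)
        cand = np.argwhere(loglik >= best - self.tie_margin)
        order = np.lexsort((
            -loglik[cand[:, 0], cand[:, 1]],
            -P[cand[:, 0]],
            np.round(T[cand[:, 1]]),
        ))
        pi, ti = cand[order[0]]
        purity, ploidy = float(P[pi]), float(T[ti])
        ll = float(loglik[pi, ti])
        copies = copies_by_cand[pi, ti].copy()
        while ploidy / 2.0 >= self.ploidy_grid.min() - 1e-9:
            p2 = 2.0 * purity / (1.0 + purity)
            t2 = ploidy / 2.0
            ll2_arr, c2_arr = self._grid_loglik(np.array([min(p2, 1.0)]),
                                               np.array([t2]), sd)
            if ll2_arr[0, 0] < ll - self.tie_margin:
                break
            purity, ploidy, ll = min(p2, 1.0), t2, float(ll2_arr[0, 0])
            copies = c2_arr[0, 0].copy()

        fitted = [Segment(s.start, s.end, s.mean, s.n_exons, copies=int(copies[si]))
                  for si, s in enumerate(segs)]

        # a profile indistinguishable from flat carries no purity information
        identifiable = any(
            abs(s.mean) > 3.0 * sd / np.sqrt(s.n_exons) + 0.05 for s in segs
        )
        return PurityPloidyResults(self, purity, ploidy, fitted, ll,
                                   identifiable, sd)

    def _grid_loglik(self, P: np.ndarray, T: np.ndarray, sd: float):
        """Profile log-likelihood over (purity, ploidy) candidates.

        Returns ``(loglik, copies)`` with shapes (nP, nT) and
        (nP, nT, n_segments); each segment's integer copy number (and minor
        copies, when BAFs overlap it) is profiled out by minimisation.
        """
        segs = self.segments
        nP, nT = P.size, T.size
        C = np.arange(0, self.max_copies + 1)

        # expected lr: (nP, nT, nC)
        num = P[:, None, None] * C[None, None, :] + 2.0 * (1.0 - P[:, None, None])
        den = P[:, None, None] * T[None, :, None] + 2.0 * (1.0 - P[:, None, None])
        with np.errstate(divide="ignore"):
            exp_lr = np.maximum(np.log2(num / den), LR_FLOOR)

        # per-segment BAF cost as a function of (purity, C): min over minor m
        baf_cost = None
        if self.bafs is not None and len(self.bafs):
            baf_cost = {}
            for si in range(len(segs)):
                f = self.bafs.loc[self.bafs["segment"] == si, "baf"].to_numpy(float)
                if f.size == 0:
                    continue
                cost = np.full((nP, C.size), np.inf)
                for ci, c in enumerate(C):
                    ms = np.arange(0, c // 2 + 1)
                    # expected minor fraction per (purity, m); at C=0 and
                    # purity 1 no DNA remains -- neutral 0.5 keeps the cost
                    # finite without favouring that state
                    den_b = P[:, None] * c + 2 * (1 - P[:, None])
                    with np.errstate(divide="ignore", invalid="ignore"):
                        e = (P[:, None] * ms[None, :] + (1 - P[:, None])) / den_b
                    e = np.where(den_b > 1e-12, e, 0.5)
                    # per SNP, allow either phase
                    d = np.minimum(
                        (f[None, None, :] - e[:, :, None]) ** 2,
                        (f[None, None, :] - (1 - e[:, :, None])) ** 2,
                    ).sum(axis=2)
                    cost[:, ci] = d.min(axis=1)
                baf_cost[si] = cost

        loglik = np.zeros((nP, nT))
        copies_by_cand = np.zeros((nP, nT, len(segs)), dtype=int)
        for si, s in enumerate(segs):
            resid2 = (s.mean - exp_lr) ** 2  # (nP, nT, nC)
            cost = s.n_exons * resid2 / (2.0 * sd * sd)
            if baf_cost is not None and si in baf_cost:
                cost = cost + self.baf_weight * baf_cost[si][:, None, :] / (
                    2.0 * self.baf_sd ** 2)
            best_c = np.argmin(cost, axis=2)
            loglik -= np.take_along_axis(cost, best_c[:, :, None], axis=2)[:, :, 0]
            copies_by_cand[:, :, si] = best_c
        return loglik, copies_by_cand


class PurityPloidyResults:
    def __init__(self, model, purity, ploidy, segments, loglik, identifiable, lr_sd):
        self.model = model
        self.purity = purity if identifiable else None
        self.ploidy = ploidy if identifiable else None
        self.segments = segments
        self.loglik = loglik
        self.identifiable = identifiable
        self.lr_sd = lr_sd

    @property
    def segment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start": s.start, "end": s.end, "n_exons": s.n_exons,
              "seg_mean": s.mean, "copies": s.copies} for s in self.segments]
        )

    def summary(self) -> str:
        head = [
            "Purity/ploidy fit",
            f"  identifiable : {self.identifiable}",
            f"  purity       : {self.purity if self.purity is not None else 'unknown'}",
            f"  tumor ploidy : {self.ploidy if self.ploidy is not None else 'unknown'}",
            f"  log-lik      : {self.loglik:.3f}",
            f"  lr noise sd  : {self.lr_sd:.4f}",
            "",
        ]
        return "\n".join(head) + self.segment_table.to_string(index=False)

    def to_dict(self) -> dict:
        return {
            "purity": self.purity, "ploidy": self.ploidy,
            "identifiable": self.identifiable, "loglik": self.loglik,
            "segments": [
                {"start": s.start, "end": s.end, "n_exons": s.n_exons,
                 "mean": s.mean, "copies": s.copies} for s in self.segments
            ],
        }


def fit_purity_ploidy(segments, bafs=None, **kw) -> PurityPloidyResults:
    """Functional wrapper over :class:`PurityPloidyModel`."""
    return PurityPloidyModel(segments, bafs=bafs, **kw).fit()


def call_focal_cnas(
    fit: PurityPloidyResults,
    gene_exons: dict,
    purity_gate: float = PURITY_GATE,
    log: list | None = None,
) -> list[CnaCall]:
    """Gene-level focal amplification / homozygous deletion calls.

    ``gene_exons`` maps gene -> iterable of exon indices (profile order).
    The gene copy number is the modal segment copy number over its exons,
    ties broken toward the more extreme value.  No calls are emitted from
    unidentifiable fits or samples at purity <= 20%.
    """
    if not fit.identifiable:
        if log is not None:
            log.append("no CNA calls: purity/ploidy fit unidentifiable")
        return []
    if fit.purity is None or fit.purity <= purity_gate:
        if log is not None:
            log.append(f"no CNA calls: purity {fit.purity} <= gate {purity_gate}")
        return []
    seg_of_exon = {}
    for si, s in enumerate(fit.segments):
        for e in s.exon_range:
            seg_of_exon[e] = si
    calls: list[CnaCall] = []
    for gene, exon_idx in gene_exons.items():
        segs = [seg_of_exon[e] for e in exon_idx if e in seg_of_exon]
        if not segs:
            if log is not None:
                log.append(f"gene {gene}: no exons in profile; skipped")
            continue
        copies = [fit.segments[si].copies for si in segs]
        vals, cnt = np.unique(copies, return_counts=True)
        modal = vals[cnt == cnt.max()]
        # among equally frequent copy states prefer the more extreme one
        c = int(modal[np.argmax(np.abs(modal - 2))])
        seg_ref = segs[copies.index(c)]
        if c >= AMPLIFICATION_COPIES:
            calls.append(CnaCall(gene, "amplification", c, seg_ref))
        elif c == DELETION_COPIES:
            calls.append(CnaCall(gene, "homozygous_deletion", c, seg_ref))
    return calls
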