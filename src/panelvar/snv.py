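"""Bayesian base-substitution detection.

The caller evaluates, at each pileup site, the posterior probability that a
somatic substitution is present given the observed four-allele read counts:

    P(mutation present | R) = P(F > 0 | R)

where F is the mutant allele fraction.  The read data R enter through a
multinomial likelihood over the four nucleotide counts whose per-allele
probabilities mix the candidate fraction F with a per-base sequencing error
rate spread uniformly over the three non-truth alleles.  The prior mass on
"no mutation", P(F=0), is site-specific: recurrently mutated (hotspot) sites
receive a lower P(F=0), which raises sensitivity exactly where somatic
mutations are expected; the proportionality in the model is resolved by
normalising over a discrete grid of candidate fractions carrying the
remaining prior mass uniformly.

Candidate calls are then passed through quality filters (strand bias, read
location bias, a blacklist of recurrent artifacts from normal controls) and
classified against germline and known-somatic site lists.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact as _scipy_fisher

ALLELES = ("A", "C", "G", "T")
ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

# Prior mass on "no mutation" by annotation class.  The ordering (hotspot <
# tissue-elevated < default) is the operative contract; the magnitudes are
# configurable defaults.
DEFAULT_P_NO_MUTATION = 0.999
TISSUE_P_NO_MUTATION = 0.99
HOTSPOT_P_NO_MUTATION = 0.9

DEFAULT_BASE_ERROR = 1e-3
POSTERIOR_CALL_THRESHOLD = 0.99
MIN_VARIANT_READS = 3


def default_frequency_grid(n: int = 50, low: float = 0.005, high: float = 1.0) -> np.ndarray:
    """Log-spaced candidate mutant fractions used to normalise the posterior."""
    return np.geomspace(low, high, n)


@dataclass
class PileupCounts:
    """Per-site allele x strand read counts plus variant read-position summary.

    ``counts`` is a (4, 2) array: rows A,C,G,T; columns forward, reverse.
    ``offset_mean``/``offset_disp`` summarise where variant bases sit within
    their reads (fraction of read length; dispersion = variance), the
    sufficient statistics for the read-location-bias filter.
    """

    contig: str
    pos: int  # 1-based
    ref: str
    counts: np.ndarray
    offset_mean: float | None = None
    offset_disp: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 2):
            raise ValueError("counts must be a 4x2 (allele x strand) array")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if self.ref not in ALLELE_INDEX:
            raise ValueError(f"reference allele {self.ref!r} not in ACGT")

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    @property
    def allele_counts(self) -> np.ndarray:
        """Strand-collapsed counts in A,C,G,T order."""
        return self.counts.sum(axis=1)

    def best_alt(self) -> str:
        """Non-reference allele with the highest read support."""
        ac = self.allele_counts.copy()
        ac[ALLELE_INDEX[self.ref]] = -1
        return ALLELES[int(np.argmax(ac))]

    def alt_count(self, alt: str | None = None) -> int:
        alt = alt or self.best_alt()
        return int(self.allele_counts[ALLELE_INDEX[alt]])


@dataclass(frozen=True)
class SitePrior:
    """Prior probability of no mutation, P(F=0), at a site."""

    p_no_mutation: float = DEFAULT_P_NO_MUTATION
    hotspot: bool = False
    source: str = "default"  # default | tissue | hotspot

    def __post_init__(self) -> None:
        if not (0.0 < self.p_no_mutation <= 1.0):
            raise ValueError("p_no_mutation must be in (0, 1]")
        if self.hotspot and self.p_no_mutation >= DEFAULT_P_NO_MUTATION:
            raise ValueError("hotspot prior must be below the default prior")

    @classmethod
    def hotspot_prior(cls) -> "SitePrior":
        return cls(HOTSPOT_P_NO_MUTATION, hotspot=True, source="hotspot")

    @classmethod
    def tissue_prior(cls) -> "SitePrior":
        return cls(TISSUE_P_NO_MUTATION, hotspot=False, source="tissue")


@dataclass
class PosteriorResult:
    posterior_mutation: float
    maf_estimate: float
    alt: str
    alt_count: int
    frequency_grid: np.ndarray = field(repr=False)


@dataclass
class SiteDatabases:
    """Surrogates for the external annotation resources.

    ``artifact_sites`` plays the role of a recurrent-artifact blacklist built
    from normal controls; ``germline_sites`` a dbSNP-like germline list;
    ``somatic_sites`` a COSMIC-like known-somatic list mapping
    (contig, pos, alt) -> hotspot flag.  A site may occur in several lists;
    lookups are exact on (contig, position, alt allele).
    """

    artifact_sites: set = field(default_factory=set)
    germline_sites: set = field(default_factory=set)
    somatic_sites: dict = field(default_factory=dict)

    @staticmethod
    def key(contig: str, pos: int, alt: str) -> tuple:
        return (str(contig), int(pos), str(alt))

    def is_artifact(self, contig, pos, alt) -> bool:
        return self.key(contig, pos, alt) in self.artifact_sites

    def is_germline(self, contig, pos, alt) -> bool:
        return self.key(contig, pos, alt) in self.germline_sites

    def somatic_hotspot(self, contig, pos, alt):
        """None if unknown to the somatic list, else the hotspot flag."""
        return self.somatic_sites.get(self.key(contig, pos, alt))


@dataclass
class VariantCall:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf_estimate: float
    posterior: float
    alt_reads: int = 0
    depth: int = 0
    filters: dict = field(default_factory=dict)  # name -> bool (True = failed)
    somatic_status: str = "unknown"
    consequence: str | None = None

    @property
    def passed(self) -> bool:
        return not any(self.filters.values())

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def site(self) -> tuple:
        return (self.contig, self.pos, self.alt)


def _allele_probs(F: np.ndarray, ref_idx: int, alt_idx: int, base_error: float) -> np.ndarray:
    """Observed-allele probabilities for each candidate fraction.

    A sequenced base derives from the reference allele with probability 1-F
    and the mutant allele with probability F; a sequencing error replaces the
    true base by one of the other three alleles, each with probability e/3.
    Returns an array of shape (len(F), 4).
    """
    F = np.atleast_1d(np.asarray(F, dtype=float))
    q = np.zeros((F.size, 4))
    q[:, ref_idx] = 1.0 - F
    q[:, alt_idx] += F
    e = base_error
    return q * (1.0 - e) + (1.0 - q) * (e / 3.0)


def log_multinomial(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Log multinomial pmf of 4-allele ``counts`` under rows of ``probs``.

    Zero-probability cells contribute -inf only when their count is non-zero.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    coeff = gammaln(n + 1.0) - gammaln(counts + 1.0).sum()
    probs = np.atleast_2d(probs)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(counts > 0, counts * np.log(probs), 0.0)
    return coeff + lp.sum(axis=1)


def mutation_posterior(
    counts: PileupCounts,
    prior: SitePrior | None = None,
    base_error: float = DEFAULT_BASE_ERROR,
    grid: np.ndarray | None = None,
    alt: str | None = None,
) -> PosteriorResult:
    """Posterior probability that a substitution is present at this site.

    The posterior is normalised over the discrete frequency grid G:

        Z = P(R|F=0) P(F=0) + sum_{f in G} P(R|F=f) (1 - P(F=0)) / |G|
        P(F>0 | R) = 1 - P(R|F=0) P(F=0) / Z

    and the allele-fraction estimate is the grid argmax of the likelihood.
    When ``alt`` is not given every non-reference allele is evaluated and the
    best-supported one (highest posterior, ties to higher count) is returned.
    """
    prior = prior or SitePrior()
    if counts.depth == 0:
        raise ValueError("mutation_posterior requires non-zero depth")
    grid = default_frequency_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty frequency grid")
    if (grid <= 0).any() or (grid > 1).any() or (np.diff(grid) <= 0).any():
        raise ValueError("grid must be sorted and within (0, 1]")

    ref_idx = ALLELE_INDEX[counts.ref]
    ac = counts.allele_counts
    cand = [alt] if alt is not None else [a for a in ALLELES if a != counts.ref]

    best: PosteriorResult | None = None
    for a in cand:
        alt_idx = ALLELE_INDEX[a]
        p0 = _allele_probs(np.array([0.0]), ref_idx, alt_idx, base_error)
        ll0 = log_multinomial(ac, p0)[0]
        llf = log_multinomial(ac, _allele_probs(grid, ref_idx, alt_idx, base_error))
        log_h0 = ll0 + math.log(prior.p_no_mutation)
        if prior.p_no_mutation < 1.0:
            log_h1 = llf + math.log1p(-prior.p_no_mutation) - math.log(grid.size)
            log_z = logsumexp(np.append(log_h1, log_h0))
            posterior = float(-np.expm1(log_h0 - log_z))
        else:
            posterior = 0.0
        posterior = min(max(posterior, 0.0), 1.0)
        maf = float(grid[int(np.argmax(llf))]) if ac[alt_idx] > 0 else 0.0
        res = PosteriorResult(posterior, maf, a, int(ac[alt_idx]), grid)
        if best is None or (res.posterior_mutation, res.alt_count) > (
            best.posterior_mutation, best.alt_count
        ):
            best = res
    return best


def strand_bias_filter(
    counts: PileupCounts,
    significance: float = 1e-3,
    alt: str | None = None,
    min_depth: int = 10,
    minor_strand_floor: float = 0.05,
) -> tuple[bool, float]:
    """Fisher's exact test of allele x strand association.

    Returns ``(passed, p_value)``.  A site fails only when the association is
    significant AND the variant reads are effectively one-stranded (minor
    strand carrying < 5% of variant reads).  Sites with too little data to
    assess bias always pass.
    """
    if counts.depth == 0:
        raise ValueError("strand_bias_filter requires non-zero depth")
    alt = alt or counts.best_alt()
    ref_idx, alt_idx = ALLELE_INDEX[counts.ref], ALLELE_INDEX[alt]
    table = np.array([counts.counts[ref_idx], counts.counts[alt_idx]])
    alt_total = table[1].sum()
    if counts.depth < min_depth or alt_total < 2:
        return True, 1.0
    _, p = _scipy_fisher(table)
    minor_frac = table[1].min() / alt_total
    failed = (p < significance) and (minor_frac < minor_strand_floor)
    return (not failed), float(p)


def position_bias_filter(
    counts: PileupCounts,
    edge_fraction: float = 0.10,
    dispersion_floor: float = 0.01,
) -> tuple[bool, bool]:
    """Flag variants whose supporting bases cluster at read ends.

    Returns ``(passed, warning)``.  Fails when the mean variant offset lies
    within ``edge_fraction`` of either read end and the offset dispersion is
    below ``dispersion_floor`` (tight clustering, the signature of an
    alignment artifact).  A missing summary passes with a warning.
    """
    m, d = counts.offset_mean, counts.offset_disp
    if m is None or d is None or not np.isfinite(m) or not np.isfinite(d):
        return True, True
    near_edge = m < edge_fraction or m > 1.0 - edge_fraction
    return (not (near_edge and d < dispersion_floor)), False


def classify_somatic(call: VariantCall, dbs: SiteDatabases) -> str:
    """Germline/somatic classification with known-somatic precedence.

    A site recorded as somatic in other tumors is never germline-filtered,
    even if it also appears in the germline list.
    """
    if dbs.somatic_hotspot(call.contig, call.pos, call.alt) is not None:
        return "known_somatic"
    if dbs.is_germline(call.contig, call.pos, call.alt):
        return "filtered_germline"
    if call.consequence in ("truncating", "frameshift", "nonsense", "splice"):
        return "likely_somatic_or_functional"
    return "unknown"


def site_prior_for(contig, pos, alt, dbs: SiteDatabases | None,
                   priors: dict | None = None) -> SitePrior:
    """Resolve the site prior: explicit table > hotspot annotation > default."""
    if priors is not None:
        explicit = priors.get((str(contig), int(pos)))
        if explicit is not None:
            return explicit
    if dbs is not None:
        hot = dbs.somatic_hotspot(contig, pos, alt)
        if hot:
            return SitePrior.hotspot_prior()
        if hot is not None:
            return SitePrior.tissue_prior()
    return SitePrior()


def call_variants(
    pileups: list[PileupCounts],
    priors: dict | None = None,
    dbs: SiteDatabases | None = None,
    base_error: float = DEFAULT_BASE_ERROR,
    grid: np.ndarray | None = None,
    posterior_threshold: float = POSTERIOR_CALL_THRESHOLD,
    min_variant_reads: int = MIN_VARIANT_READS,
    panel=None,
    log: list | None = None,
) -> list[VariantCall]:
    """Run the full substitution-calling chain over a pileup table.

    Emits the sites whose posterior clears the call threshold with the
    required read support, all quality filters passing, not germline-filtered
    and not on the artifact blacklist; sorted by (contig, position).
    ``priors`` maps (contig, pos) -> SitePrior for explicit overrides.
    """
    dbs = dbs or SiteDatabases()
    calls: list[VariantCall] = []
    for pu in pileups:
        if panel is not None and not panel.contains(pu.contig, pu.pos):
            if log is not None:
                log.append(f"site {pu.contig}:{pu.pos} outside panel; skipped")
            continue
        if pu.depth == 0:
            continue
        alt0 = pu.best_alt()
        prior = site_prior_for(pu.contig, pu.pos, alt0, dbs, priors)
        post = mutation_posterior(pu, prior, base_error=base_error, grid=grid)
        if post.posterior_mutation < posterior_threshold:
            continue
        if post.alt_count < min_variant_reads:
            continue
        sb_pass, sb_p = strand_bias_filter(pu, alt=post.alt)
        pb_pass, _ = position_bias_filter(pu)
        artifact = dbs.is_artifact(pu.contig, pu.pos, post.alt)
        call = VariantCall(
            contig=pu.contig, pos=pu.pos, ref=pu.ref, alt=post.alt,
            maf_estimate=post.maf_estimate, posterior=post.posterior_mutation,
            alt_reads=post.alt_count, depth=pu.depth,
            filters={"strand_bias": not sb_pass,
                     "position_bias": not pb_pass,
                     "artifact": artifact},
        )
        call.somatic_status = classify_somatic(call, dbs)
        call.filters["germline"] = call.somatic_status == "filtered_germline"
        if artifact and log is not None:
            log.append(f"site {pu.contig}:{pu.pos} {pu.ref}>{post.alt} on artifact blacklist")
        if call.passed:
            calls.append(call)
    calls.sort(key=lambda c: (c.contig, c.pos))
    return calls


class SomaticSubstitutionModel:
    """Model interface over the Bayesian substitution caller.

    Construct from a list of :class:`PileupCounts` (or a pileup DataFrame via
    :meth:`from_dataframe`), then ``fit()`` to obtain a
    :class:`SubstitutionResults` holding the emitted calls.
    """

    def __init__(self, pileups, priors=None, databases=None,
                 base_error=DEFAULT_BASE_ERROR, grid=None,
                 posterior_threshold=POSTERIOR_CALL_THRESHOLD,
                 min_variant_reads=MIN_VARIANT_READS, panel=None):
        self.pileups = list(pileups)
        self.priors = priors
        self.databases = databases or SiteDatabases()
        self.base_error = base_error
        self.grid = default_frequency_grid() if grid is None else np.asarray(grid)
        self.posterior_threshold = posterior_threshold
        self.min_variant_reads = min_variant_reads
        self.panel = panel

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "SomaticSubstitutionModel":
        from .tables import pileups_from_frame

        return cls(pileups_from_frame(df), **kw)

    def fit(self) -> "SubstitutionResults":
        log: list[str] = []
        calls = call_variants(
            self.pileups, priors=self.priors, dbs=self.databases,
            base_error=self.base_error, grid=self.grid,
            posterior_threshold=self.posterior_threshold,
            min_variant_reads=self.min_variant_reads, panel=self.panel, log=log,
        )
        return SubstitutionResults(self, calls, log)


class SubstitutionResults:
    def __init__(self, model: SomaticSubstitutionModel, calls: list[VariantCall], log):
        self.model = model
        self.calls = calls
        self.log = log

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "contig": c.contig, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "maf": c.maf_estimate, "posterior": c.posterior,
                "alt_reads": c.alt_reads, "depth": c.depth,
                "somatic_status": c.somatic_status,
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows, columns=["contig", "pos", "ref", "alt", "maf", "posterior",
                           "alt_reads", "depth", "somatic_status"],
        )

    def summary(self) -> str:
        lines = [
            "Somatic substitution calls",
            f"  sites examined : {len(self.model.pileups)}",
            f"  calls emitted  : {len(self.calls)}",
            f"  posterior >= {self.model.posterior_threshold}, "
            f">= {self.model.min_variant_reads} variant reads",
            "",
        ]
        if self.calls:
            lines.append(self.table.to_string(index=False))
        return "\n".join(lines)
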