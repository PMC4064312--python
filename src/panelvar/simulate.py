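"""Ground-truthed synthetic data for every downstream stage.

Emulates a two-group targeted-sequencing tumor cohort: per-site allele
pileups with per-base error, exon log-ratio profiles under the purity/ploidy
mixture model, heterozygous-SNP allele fractions, short reads with injected
indels, per-sample viral read tallies, and group-specific gene alteration
prevalences.  Every emitted signal traces back to one ground-truth record.

All generators accept either an integer seed or a ``numpy.random.Generator``
and are byte-identical under a fixed seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cna import LogRatioProfile, expected_baf, expected_logratio
from .panel import TargetPanel, default_panel
from .snv import ALLELES, ALLELE_INDEX, PileupCounts

__all__ = [
    "CohortSpec", "GroundTruth", "SampleTruth", "simulate_pileup",
    "simulate_logratio_profile", "simulate_snp_bafs", "simulate_exon_reads",
    "simulate_cohort", "figure_like_prevalences",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def figure_like_prevalences() -> dict:
    """Two-group alteration prevalences emulating the published cohort.

    Group A plays the HPV-positive stratum, group B the HPV-negative one:
    TP53 mutation in all of group B (one low-impact exception rate in A),
    CCND1 amplification and CDKN2A/B deletion exclusive to group B, and
    PI3K-pathway alterations enriched in group A.
    """
    return {
        "TP53": (0.056, 1.00, "mutation"),
        "CCND1": (0.00, 0.55, "amplification"),
        "CDKN2A": (0.00, 0.40, "deletion"),
        "CDKN2B": (0.00, 0.40, "deletion"),
        "PIK3CA": (0.35, 0.15, "mutation"),
        "PTEN": (0.25, 0.15, "deletion"),
        "FBXW7": (0.15, 0.15, "mutation"),
        "SOX2": (0.17, 0.06, "amplification"),
        "NOTCH1": (0.11, 0.12, "mutation"),
        "STK11": (0.11, 0.00, "mutation"),
    }


@dataclass
class CohortSpec:
    """Design of a simulated two-group cohort.

    ``gene_prevalence`` maps gene -> (prevalence in group A, prevalence in
    group B, alteration kind in {mutation, amplification, deletion}).
    """

    n_group_a: int = 20
    n_group_b: int = 20
    panel: TargetPanel | None = None
    gene_prevalence: dict = field(default_factory=figure_like_prevalences)
    purity_range: tuple = (0.4, 0.9)
    ploidy_range: tuple = (2.0, 2.0)
    depth_mean: float = 500.0
    base_error_rate: float = 1e-3
    lr_noise_sd: float = 0.15
    baf_depth: int = 100
    snps_per_gene: int = 4
    null_sites_per_gene: int = 1
    viral_rpm_positive: tuple = (20.0, 400.0)
    viral_rpm_negative: tuple = (0.0, 1.5)
    total_read_pairs: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = default_panel()
        if self.n_group_a < 0 or self.n_group_b < 0:
            raise ValueError("group sizes must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0, 1]")
        for gene, (pa, pb, kind) in self.gene_prevalence.items():
            if not (0 <= pa <= 1 and 0 <= pb <= 1):
                raise ValueError(f"{gene}: prevalences must be in [0, 1]")
            if kind not in ("mutation", "amplification", "deletion"):
                raise ValueError(f"{gene}: unknown alteration kind {kind!r}")

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = json.load(fh)
        if "gene_prevalence" in raw:
            raw["gene_prevalence"] = {
                g: tuple(v) for g, v in raw["gene_prevalence"].items()
            }
        for key in ("purity_range", "ploidy_range", "viral_rpm_positive",
                    "viral_rpm_negative"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SampleTruth:
    sample: str
    group: str  # "A" (HPV+) or "B" (HPV-)
    purity: float
    ploidy: float
    variants: list = field(default_factory=list)  # dicts: gene/contig/pos/ref/alt/maf
    gene_copies: dict = field(default_factory=dict)  # gene -> integer copies
    viral_rpm: float = 0.0
    viral_reads: int = 0
    total_reads: int = 0


@dataclass
class GroundTruth:
    samples: list  # of SampleTruth

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in self.samples], fh, indent=1)

    def sample(self, name: str) -> SampleTruth:
        return next(s for s in self.samples if s.sample == name)


def simulate_pileup(
    depth: int,
    true_maf: float,
    base_error: float,
    strand_balance: float = 0.5,
    seed=None,
    contig: str = "chr1",
    pos: int = 100,
    ref: str = "C",
    alt: str = "T",
    alt_strand_balance: float | None = None,
) -> PileupCounts:
    """Draw a multinomial pileup at a site with true mutant fraction ``true_maf``.

    Each read's true allele is ref with probability 1-maf and alt with
    probability maf; sequencing error moves it to each of the other three
    alleles with probability ``base_error``/3.  Strand is Bernoulli
    (``strand_balance``) independent of allele unless ``alt_strand_balance``
    is set, which biases variant reads for strand-filter testing.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not (0.0 <= true_maf <= 1.0):
        raise ValueError("true_maf must be in [0, 1]")
    if not (0.0 <= base_error < 0.25):
        raise ValueError("base_error must be in [0, 0.25)")
    rng = _rng(seed)
    ref_i, alt_i = ALLELE_INDEX[ref], ALLELE_INDEX[alt]
    if ref_i == alt_i:
        raise ValueError("ref and alt alleles must differ")

    q = np.zeros(4)
    q[ref_i], q[alt_i] = 1.0 - true_maf, true_maf
    p_allele = q * (1.0 - base_error) + (1.0 - q) * (base_error / 3.0)
    sb = np.full(4, strand_balance)
    if alt_strand_balance is not None:
        sb[alt_i] = alt_strand_balance
    p8 = np.stack([p_allele * sb, p_allele * (1.0 - sb)], axis=1)
    counts = np.zeros((4, 2), dtype=np.int64)
    if depth > 0:
        counts = rng.multinomial(depth, p8.ravel()).reshape(4, 2)

    n_alt = int(counts[alt_i].sum())
    if n_alt > 0:
        offsets = rng.uniform(size=n_alt)
        om, od = float(offsets.mean()), float(offsets.var())
    else:
        om = od = float("nan")
    return PileupCounts(contig, pos, ref, counts, offset_mean=om, offset_disp=od)


def simulate_logratio_profile(
    copy_profile,
    purity: float,
    ploidy: float,
    noise_sd: float,
    seed=None,
    exons: pd.DataFrame | None = None,
) -> LogRatioProfile:
    """Forward-simulate per-exon log2 tumor/normal ratios.

    Each exon's value is the mixture-model expectation
    log2[(p*C + 2(1-p)) / (p*ploidy + 2(1-p))] plus Gaussian noise.
    """
    copies = np.asarray(copy_profile, dtype=float)
    if (copies < 0).any():
        raise ValueError("copy numbers must be non-negative")
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    rng = _rng(seed)
    mu = expected_logratio(copies, purity, ploidy)
    lr = mu + (rng.normal(0.0, noise_sd, size=copies.size) if noise_sd > 0 else 0.0)
    return LogRatioProfile(lr=np.asarray(lr, dtype=float), exons=exons)


def simulate_snp_bafs(
    copy_profile,
    minor_copies,
    purity: float,
    n_snps: int,
    depth: int,
    seed=None,
    segment_index=None,
) -> pd.DataFrame:
    """Heterozygous-SNP alt-allele fractions under copy state and purity.

    SNPs are spread round-robin over the entries of ``copy_profile`` (one
    copy state per entry, e.g. per segment); alt counts are binomial around
    (p*m + (1-p)) / (p*C + 2(1-p)) with random phase, so the returned ``baf``
    may be the major- or minor-allele fraction.
    """
    copies = np.asarray(copy_profile, dtype=float)
    minor = np.asarray(minor_copies, dtype=float)
    if copies.shape != minor.shape:
        raise ValueError("copy_profile and minor_copies must align")
    if (minor > copies).any():
        raise ValueError("minor copies cannot exceed total copies")
    rng = _rng(seed)
    rows = []
    for i in range(n_snps):
        j = i % copies.size
        e = expected_baf(copies[j], minor[j], purity)
        if rng.random() < 0.5:  # phase: which parental allele is "alt"
            e = 1.0 - e
        alt = rng.binomial(depth, e)
        rows.append({
            "snp": f"snp{i:04d}",
            "segment": int(segment_index[j]) if segment_index is not None else j,
            "depth": depth,
            "alt_reads": int(alt),
            "baf": alt / depth if depth else float("nan"),
        })
    return pd.DataFrame(rows)


def apply_variant(window: str, variant: dict | None) -> str:
    """Apply a substitution/insertion/deletion spec to a reference window.

    ``variant``: {"kind": sub|ins|del, "offset": 0-based, "alt"/"length"}.
    Insertions are placed after the offset base; deletions remove ``length``
    bases starting at offset+1 (anchored convention).
    """
    if variant is None:
        return window
    kind, off = variant["kind"], variant["offset"]
    if kind == "sub":
        return window[:off] + variant["alt"] + window[off + 1:]
    if kind == "ins":
        return window[: off + 1] + variant["alt"] + window[off + 1:]
    if kind == "del":
        ln = variant["length"]
        return window[: off + 1] + window[off + 1 + ln:]
    raise ValueError(f"unknown variant kind {kind!r}")


def simulate_exon_reads(
    reference_window: str,
    variant: dict | None,
    depth: int,
    read_length: int,
    base_error: float = 0.0,
    variant_fraction: float = 0.5,
    seed=None,
) -> list[tuple[str, str]]:
    """Uniformly tiling reads over an exon window, a fraction from the
    variant haplotype.

    ``depth`` is the target mean per-base fold-coverage (matching the
    pileup-depth convention), so the number of reads drawn is
    ``depth * window_length / read_length``.  Returns ``(name, sequence)``
    pairs; read start positions are uniform over the haplotype each read is
    drawn from, and substitution errors are injected at ``base_error`` per
    base.
    """
    if read_length >= len(reference_window):
        raise ValueError("read_length must be shorter than the window")
    if variant is not None and variant.get("length", len(variant.get("alt", ""))) >= read_length / 2:
        raise ValueError("variant length must be < read_length / 2")
    rng = _rng(seed)
    alt_window = apply_variant(reference_window, variant)
    reads = []
    n_reads = int(round(depth * len(reference_window) / read_length))
    for i in range(n_reads):
        from_alt = variant is not None and rng.random() < variant_fraction
        hap = alt_window if from_alt else reference_window
        start = int(rng.integers(0, len(hap) - read_length + 1))
        seq = list(hap[start: start + read_length])
        if base_error > 0:
            err = rng.random(read_length) < base_error
            for j in np.nonzero(err)[0]:
                choices = [b for b in "ACGT" if b != seq[j]]
                seq[j] = choices[int(rng.integers(0, 3))]
        reads.append((f"read{i:05d}/{'alt' if from_alt else 'ref'}", "".join(seq)))
    return reads


def _draw_variant_site(rng, panel: TargetPanel, gene: str) -> tuple[str, int, str, str]:
    idx = panel.gene_exon_indices()[gene]
    exon = panel.exons.iloc[int(rng.choice(idx))]
    pos = int(rng.integers(exon.start + 1, exon.end + 1))  # 1-based within exon
    ref = ALLELES[int(rng.integers(0, 4))]
    alt = [a for a in ALLELES if a != ref][int(rng.integers(0, 3))]
    return exon.contig, pos, ref, alt


def simulate_cohort(spec: CohortSpec):
    """Simulate a full two-group cohort.

    Returns ``(bundles, truth)`` where ``bundles`` maps sample name -> dict
    with keys ``pileups`` (list of PileupCounts), ``logratio``
    (LogRatioProfile), ``bafs`` (DataFrame), ``viral`` (dict) and ``group``;
    ``truth`` is the matching :class:`GroundTruth`.
    """
    rng = _rng(spec.seed)
    panel = spec.panel
    gene_idx = panel.gene_exon_indices()
    n_exons = len(panel)
    bundles: dict[str, dict] = {}
    truths: list[SampleTruth] = []

    names = [f"S{i + 1:02d}_A" for i in range(spec.n_group_a)] + [
        f"S{i + 1:02d}_B" for i in range(spec.n_group_b)
    ]
    groups = ["A"] * spec.n_group_a + ["B"] * spec.n_group_b

    for name, group in zip(names, groups):
        purity = float(rng.uniform(*spec.purity_range))
        ploidy = float(rng.uniform(*spec.ploidy_range))
        background = int(round(ploidy))
        copies = np.full(n_exons, background, dtype=int)
        minor = np.maximum(background // 2, 0) * np.ones(n_exons, dtype=int)
        gene_copies = {g: background for g in panel.genes}
        variants = []
        pileups: list[PileupCounts] = []

        for gene, (pa, pb, kind) in spec.gene_prevalence.items():
            if gene not in gene_idx:
                continue
            prev = pa if group == "A" else pb
            if rng.random() >= prev:
                continue
            if kind == "mutation":
                contig, pos, ref, alt = _draw_variant_site(rng, panel, gene)
                # one mutated copy out of C tumor copies, clonal; cellular
                # mixture scales the observed mutant fraction
                c = gene_copies[gene]
                maf = purity * 1.0 / (purity * c + 2.0 * (1.0 - purity))
                depth = max(int(rng.poisson(spec.depth_mean)), 30)
                pu = simulate_pileup(depth, maf, spec.base_error_rate, seed=rng,
                                     contig=contig, pos=pos, ref=ref, alt=alt)
                pileups.append(pu)
                variants.append({"gene": gene, "contig": contig, "pos": pos,
                                 "ref": ref, "alt": alt, "maf": maf})
            elif kind == "amplification":
                gene_copies[gene] = 8
                copies[gene_idx[gene]] = 8
                minor[gene_idx[gene]] = 1
            else:  # homozygous deletion
                gene_copies[gene] = 0
                copies[gene_idx[gene]] = 0
                minor[gene_idx[gene]] = 0

        # error-only sites provide the specificity background
        for gene in panel.genes:
            for _ in range(spec.null_sites_per_gene):
                contig, pos, ref, alt = _draw_variant_site(rng, panel, gene)
                depth = max(int(rng.poisson(spec.depth_mean)), 30)
                pileups.append(simulate_pileup(depth, 0.0, spec.base_error_rate,
                                               seed=rng, contig=contig, pos=pos,
                                               ref=ref, alt=alt))

        profile = simulate_logratio_profile(copies, purity, ploidy,
                                            spec.lr_noise_sd, seed=rng,
                                            exons=panel.exons)
        bafs = simulate_snp_bafs(copies, minor, purity,
                                 n_snps=spec.snps_per_gene * len(panel.genes),
                                 depth=spec.baf_depth, seed=rng)
        rpm_range = (spec.viral_rpm_positive if group == "A"
                     else spec.viral_rpm_negative)
        rpm_true = float(rng.uniform(*rpm_range))
        viral_reads = int(rng.poisson(rpm_true * spec.total_read_pairs / 1e6))
        truth = SampleTruth(
            sample=name, group=group, purity=purity, ploidy=ploidy,
            variants=variants, gene_copies=gene_copies,
            viral_rpm=1e6 * viral_reads / spec.total_read_pairs,
            viral_reads=viral_reads, total_reads=spec.total_read_pairs,
        )
        truths.append(truth)
        bundles[name] = {
            "group": group,
            "pileups": pileups,
            "logratio": profile,
            "bafs": bafs,
            "viral": {"virus": "HPV-16", "viral_reads": viral_reads,
                      "total_reads": spec.total_read_pairs},
        }
    return bundles, GroundTruth(truths)
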