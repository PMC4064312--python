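"""End-to-end orchestration: simulate -> call -> cohort.

``RunConfig`` is the structured, JSON-round-trippable parameter set for a
whole run; ``run_pipeline`` executes every per-sample caller and the cohort
stage, writing per-sample VCF/SEG/HPV outputs and cohort tables plus a
structured log of the resolved parameters and seeds.  Re-running with the
same config and inputs reproduces byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cna import PurityPloidyModel, call_focal_cnas, segment_profile
from .cohort import CohortModel
from .simulate import CohortSpec, simulate_cohort
from .snv import SomaticSubstitutionModel
from .tables import write_pileups, write_bafs, write_seg
from .vcfio import write_vcf
from .viral import ViralReadReport

KNOWN_KEYS = {
    "seed", "posterior_threshold", "min_variant_reads", "base_error",
    "purity_gate", "segment_penalty", "baf_weight", "cohort",
    "write_heatmap",
}


@dataclass
class RunConfig:
    seed: int = 0
    posterior_threshold: float = 0.99
    min_variant_reads: int = 3
    base_error: float = 1e-3
    purity_gate: float = 0.20
    segment_penalty: float | None = None
    baf_weight: float = 1.0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    write_heatmap: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def run_pipeline(config: RunConfig, out_dir, bundles=None, truth=None) -> Path:
    """Run the whole analysis; simulates a cohort when no inputs are given.

    Returns the results directory, containing per-sample ``<name>.vcf``,
    ``<name>.seg``, ``<name>.fit.json``, a cohort ``hpv_status.tsv``,
    ``alteration_matrix.tsv``, ``enrichment.tsv``, ``clustering.nwk`` and
    ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "config": dataclasses.asdict(config),
                 "samples": {}, "messages": []}

    if bundles is None:
        spec = CohortSpec(seed=config.seed, **config.cohort)
        bundles, truth = simulate_cohort(spec)
        truth.to_json(out / "ground_truth.json")

    variant_calls: dict[str, list] = {}
    cna_calls: dict[str, list] = {}
    hpv_rows = []
    sheet_rows = []
    for name, bundle in sorted(bundles.items()):
        smp_log: list[str] = []
        try:
            panel_exons = bundle["logratio"].exons
            # substitutions
            model = SomaticSubstitutionModel(
                bundle["pileups"], base_error=config.base_error,
                posterior_threshold=config.posterior_threshold,
                min_variant_reads=config.min_variant_reads,
            )
            res = model.fit()
            calls = res.calls
            if panel_exons is not None:
                gene_of = _gene_lookup(panel_exons)
                for c in calls:
                    c.gene = gene_of(c.contig, c.pos)
            write_vcf(calls, out / f"{name}.vcf")
            variant_calls[name] = [c for c in calls if getattr(c, "gene", None)]

            # copy number
            profile = bundle["logratio"]
            segs = segment_profile(profile, penalty=config.segment_penalty)
            bafs = bundle.get("bafs")
            if bafs is not None and "segment" in bafs.columns:
                bafs = _rekey_baf_segments(bafs, segs)
            ppm = PurityPloidyModel(segs, bafs=bafs, profile=profile,
                                    baf_weight=config.baf_weight)
            fit = ppm.fit()
            write_seg(fit.segments, out / f"{name}.seg", sample=name,
                      exons=panel_exons)
            with open(out / f"{name}.fit.json", "w") as fh:
                json.dump(fit.to_dict(), fh, indent=1)
            gene_exons = {}
            if panel_exons is not None and "gene" in panel_exons.columns:
                gene_exons = {g: list(ix) for g, ix in
                              panel_exons.groupby("gene").groups.items()}
            cna_calls[name] = call_focal_cnas(fit, gene_exons,
                                              purity_gate=config.purity_gate,
                                              log=smp_log)

            # viral status
            v = bundle["viral"]
            rep = ViralReadReport(name, v.get("virus", "HPV-16"),
                                  v["viral_reads"], v["total_reads"])
            hpv_rows.append(rep.as_row())
            sheet_rows.append({"sample": name, "group": bundle["group"]})
            log["samples"][name] = {"n_snv": len(variant_calls[name]),
                                    "n_cna": len(cna_calls[name]),
                                    "purity": fit.purity, "ploidy": fit.ploidy,
                                    "hpv": rep.status, "messages": smp_log}
        except (KeyError, ValueError) as exc:
            log["messages"].append(f"sample {name} skipped: {exc}")
            log["samples"][name] = {"skipped": str(exc)}
    pd.DataFrame(hpv_rows).to_csv(out / "hpv_status.tsv", sep="\t", index=False)

    sheet = pd.DataFrame(sheet_rows)
    if len(sheet) >= 2 and sheet.group.nunique() == 2:
        cm = CohortModel.from_calls(variant_calls, cna_calls, sheet)
        cres = cm.fit()
        cm.matrix.data.to_csv(out / "alteration_matrix.tsv", sep="\t")
        cres.enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        if cres.clustering is not None:
            with open(out / "clustering.nwk", "w") as fh:
                fh.write(cres.clustering.to_newick())
            log["clustering_purity"] = cres.clustering.purity
        if config.write_heatmap:
            plot_alteration_matrix(cm.matrix, out / "alteration_matrix.png")

    partial = any("skipped" in s for s in log["samples"].values())
    log["complete"] = not partial
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return out


def _gene_lookup(exons: pd.DataFrame):
    if "gene" not in exons.columns:
        return lambda contig, pos: None

    def lookup(contig, pos):
        hit = exons[(exons.contig == contig) & (exons.start < pos)
                    & (pos <= exons.end)]
        return hit.iloc[0].gene if len(hit) else None

    return lookup


def _rekey_baf_segments(bafs: pd.DataFrame, segs) -> pd.DataFrame:
    """Map simulation-time per-exon segment keys onto fitted segment indices."""
    out = bafs.copy()
    exon = out["segment"].to_numpy()  # simulator keys BAFs by exon index
    seg_of_exon = {}
    for si, s in enumerate(segs):
        for e in s.exon_range:
            seg_of_exon[e] = si
    out["segment"] = [seg_of_exon.get(int(e), -1) for e in exon]
    return out[out["segment"] >= 0]


def plot_alteration_matrix(matrix, path) -> None:
    """Figure-2-style heatmap of the categorical alteration matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cats = ["none", "mutation", "amplification", "deletion", "multiple"]
    colors = ["#f0f0f0", "#2166ac", "#b2182b", "#4dac26", "#762a83"]
    order = matrix.groups.sort_values().index
    data = matrix.data.loc[order]
    codes = data.apply(lambda col: col.map({c: i for i, c in enumerate(cats)}))
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * data.shape[1]),
                                    max(4, 0.25 * data.shape[0])))
    ax.imshow(codes.to_numpy(), cmap=ListedColormap(colors), vmin=0,
              vmax=len(cats) - 1, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_sample_inputs(bundles, truth, out_dir) -> Path:
    """Write a simulated cohort to disk in the interchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, b in bundles.items():
        d = out / name
        d.mkdir(exist_ok=True)
        write_pileups(b["pileups"], d / "pileups.tsv")
        write_bafs(b["bafs"], d / "bafs.tsv")
        np.savetxt(d / "logratio.tsv", b["logratio"].lr, fmt="%.6f")
        with open(d / "viral.json", "w") as fh:
            json.dump(b["viral"], fh)
    truth.to_json(out / "ground_truth.json")
    return out
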