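"""VCF 4.2 output/input for substitution and indel calls.

Writing is plain-text (the call set is small and fully specified here);
reading goes through pysam's VariantFile so that the emitted files are
externally valid VCF.  Substitutions and assembly indels share one stream;
indels use the anchored (1-based, left-aligned) allele convention.
"""
from __future__ import annotations

import math

import pysam

from .snv import VariantCall

FILTERS = {
    "strand_bias": "Variant reads significantly one-stranded",
    "position_bias": "Variant bases clustered at read ends",
    "artifact": "Site on the recurrent-artifact blacklist",
    "germline": "Site matches the germline database",
}
INFO_LINES = [
    '##INFO=<ID=POSTERIOR,Number=1,Type=Float,Description="Posterior probability of mutation">',
    '##INFO=<ID=MAF,Number=1,Type=Float,Description="Estimated mutant allele fraction">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=ALTREADS,Number=1,Type=Integer,Description="Variant-supporting reads">',
    '##INFO=<ID=STATUS,Number=1,Type=String,Description="Somatic classification">',
]


def write_vcf(calls, path, contigs=None) -> None:
    """Write calls (sorted by contig, position) as a valid VCF 4.2 file."""
    calls = list(calls)
    order = [(c.contig, c.pos) for c in calls]
    if order != sorted(order):
        raise ValueError("calls must be sorted by (contig, position)")
    if contigs is None:
        contigs = sorted({c.contig for c in calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelvar\n")
        for name in contigs:
            fh.write(f"##contig=<ID={name}>\n")
        for fid, desc in FILTERS.items():
            fh.write(f'##FILTER=<ID={fid},Description="{desc}">\n')
        for line in INFO_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            failed = [k for k, v in c.filters.items() if v]
            filt = ";".join(failed) if failed else "PASS"
            qual = ("." if c.posterior >= 1.0
                    else f"{-10.0 * math.log10(max(1.0 - c.posterior, 1e-300)):.2f}")
            info = (f"POSTERIOR={c.posterior:.6g};MAF={c.maf_estimate:.6g};"
                    f"DP={c.depth};ALTREADS={c.alt_reads};STATUS={c.somatic_status}")
            fh.write(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\t{filt}\t{info}\n")


def read_vcf(path) -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            filters = {fid: False for fid in FILTERS}
            for fid in rec.filter.keys():
                if fid != "PASS":
                    filters[fid] = True
            info = rec.info
            calls.append(VariantCall(
                contig=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                maf_estimate=float(info.get("MAF", float("nan"))),
                posterior=float(info.get("POSTERIOR", float("nan"))),
                alt_reads=int(info.get("ALTREADS", 0)),
                depth=int(info.get("DP", 0)),
                filters=filters,
                somatic_status=str(info.get("STATUS", "unknown")),
            ))
    return calls


def indel_to_variant_call(ic, posterior: float = 1.0) -> VariantCall:
    """Represent an assembly indel in the shared VCF record type."""
    return VariantCall(
        contig=ic.contig, pos=ic.pos, ref=ic.ref, alt=ic.alt,
        maf_estimate=ic.supporting_fraction, posterior=posterior,
        somatic_status="unknown",
    )
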