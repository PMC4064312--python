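"""Tabular interchange formats: pileup, coverage, BAF and site-list TSVs.

Pileup TSV columns:
    contig  pos(1-based)  ref  A+ A- C+ C- G+ G- T+ T-  offset_mean  offset_disp
Site-list TSVs (artifact/germline/somatic databases):
    contig  pos  alt  [hotspot]
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .snv import ALLELES, PileupCounts, SiteDatabases

PILEUP_COLUMNS = (
    ["contig", "pos", "ref"]
    + [f"{a}{s}" for a in ALLELES for s in ("+", "-")]
    + ["offset_mean", "offset_disp"]
)


def pileups_to_frame(pileups) -> pd.DataFrame:
    rows = []
    for pu in pileups:
        row = {"contig": pu.contig, "pos": pu.pos, "ref": pu.ref}
        for i, a in enumerate(ALLELES):
            row[f"{a}+"] = int(pu.counts[i, 0])
            row[f"{a}-"] = int(pu.counts[i, 1])
        row["offset_mean"] = pu.offset_mean if pu.offset_mean is not None else np.nan
        row["offset_disp"] = pu.offset_disp if pu.offset_disp is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def pileups_from_frame(df: pd.DataFrame) -> list[PileupCounts]:
    out = []
    # not itertuples: "A+"-style column names are no valid identifiers
    for d in df.to_dict("records"):
        counts = np.array(
            [[d[f"{a}+"], d[f"{a}-"]] for a in ALLELES], dtype=np.int64
        )
        om = d.get("offset_mean", np.nan)
        od = d.get("offset_disp", np.nan)
        out.append(PileupCounts(str(d["contig"]), int(d["pos"]), str(d["ref"]),
                                counts,
                                offset_mean=None if pd.isna(om) else float(om),
                                offset_disp=None if pd.isna(od) else float(od)))
    return out


def write_pileups(pileups, path) -> None:
    pileups_to_frame(pileups).to_csv(path, sep="\t", index=False)


def read_pileups(path) -> list[PileupCounts]:
    df = pd.read_csv(path, sep="\t")
    # TSV round-trips "A+" columns verbatim, but guard against renamed headers
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pileup TSV missing columns: {missing}")
    return pileups_from_frame(df)


def write_coverage(exons: pd.DataFrame, coverage, path) -> None:
    df = exons[["contig", "start", "end", "gene"]].copy()
    df["coverage"] = np.asarray(coverage)
    df.to_csv(path, sep="\t", index=False)


def read_coverage(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("contig", "start", "end", "coverage"):
        if col not in df.columns:
            raise ValueError(f"coverage TSV missing column {col!r}")
    return df


def write_bafs(bafs: pd.DataFrame, path) -> None:
    bafs.to_csv(path, sep="\t", index=False)


def read_bafs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_site_databases(directory) -> SiteDatabases:
    """Load artifact/germline/somatic TSV site lists from a directory.

    Missing files yield empty lists; the somatic list's optional ``hotspot``
    column (0/1) marks elevated-prior sites.
    """
    from pathlib import Path

    directory = Path(directory)
    dbs = SiteDatabases()
    for name, target in (("artifact_sites.tsv", dbs.artifact_sites),
                         ("germline_sites.tsv", dbs.germline_sites)):
        p = directory / name
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            for r in df.itertuples(index=False):
                target.add(SiteDatabases.key(r.contig, r.pos, r.alt))
    p = directory / "somatic_sites.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        for r in df.itertuples(index=False):
            hot = bool(getattr(r, "hotspot", 0))
            dbs.somatic_sites[SiteDatabases.key(r.contig, r.pos, r.alt)] = hot
    return dbs


def write_site_databases(dbs: SiteDatabases, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, sites in (("artifact_sites.tsv", dbs.artifact_sites),
                        ("germline_sites.tsv", dbs.germline_sites)):
        pd.DataFrame(sorted(sites), columns=["contig", "pos", "alt"]).to_csv(
            directory / name, sep="\t", index=False)
    rows = [(c, p, a, int(h)) for (c, p, a), h in sorted(dbs.somatic_sites.items())]
    pd.DataFrame(rows, columns=["contig", "pos", "alt", "hotspot"]).to_csv(
        directory / "somatic_sites.tsv", sep="\t", index=False)


def write_seg(segments, path, sample: str = "sample",
              exons: pd.DataFrame | None = None) -> None:
    """SEG-format segment table (one row per fitted segment)."""
    rows = []
    for s in segments:
        if exons is not None:
            contig = exons.iloc[s.start].contig
            start = int(exons.iloc[s.start].start)
            end = int(exons.iloc[s.end - 1].end)
        else:
            contig, start, end = "NA", s.start, s.end
        rows.append({"sample": sample, "contig": contig, "start": start,
                     "end": end, "n_exons": s.n_exons, "seg_mean": s.mean,
                     "copies": s.copies})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
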