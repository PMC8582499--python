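"""Readers and writers for the plain-text formats the analysis consumes.

All tables are CSV; sequences are FASTA.  Writers emit exactly the dialect
the corresponding reader parses, so generated data round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bisulfite import MethylationMatrix
from .errors import DataError
from .msqpcr import AmplificationCurve
from .nuclei import NucleiSample
from .ploidy import KaryotypeCount

__all__ = [
    "write_methylation_csv",
    "read_methylation_csv",
    "write_curves_csv",
    "read_curves_csv",
    "read_cq_csv",
    "write_nuclei_csv",
    "read_nuclei_csv",
    "write_karyotype_csv",
    "read_karyotype_csv",
    "read_fasta",
    "read_cpg_sidecar",
]


# -- bisulfite state matrices -------------------------------------------------

def write_methylation_csv(matrices: Iterable[MethylationMatrix], path) -> None:
    """One row per molecule: molecule_id, clone_id, conversion_ok,
    CpG1..CpGn with values 1/0/NA."""
    frames = []
    for m in matrices:
        df = pd.DataFrame(m.states, columns=m.site_labels)
        df.insert(0, "conversion_ok", m.conversion_ok.astype(int))
        df.insert(0, "clone_id", m.clone_id)
        df.insert(0, "molecule_id", m.molecule_ids)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    site_cols = out.columns[3:]
    out[site_cols] = out[site_cols].astype(object).where(out[site_cols].notna(), "NA")
    for c in site_cols:
        out[c] = out[c].map(lambda v: v if v == "NA" else str(int(v)))
    out.to_csv(path, index=False)


def read_methylation_csv(path) -> list[MethylationMatrix]:
    df = pd.read_csv(path, dtype={"molecule_id": str, "clone_id": str}, na_values=["NA"])
    site_cols = [c for c in df.columns if c.startswith("CpG")]
    if not site_cols:
        raise DataError("no CpG columns found")
    matrices = []
    for clone_id, sub in df.groupby("clone_id", sort=False):
        matrices.append(
            MethylationMatrix(
                clone_id=str(clone_id),
                states=sub[site_cols].to_numpy(dtype=float),
                site_labels=site_cols,
                conversion_ok=sub["conversion_ok"].to_numpy(dtype=bool)
                if "conversion_ok" in sub
                else None,
                molecule_ids=sub["molecule_id"].tolist(),
            )
        )
    return matrices


# -- qPCR curves and Cq tables ------------------------------------------------

def write_curves_csv(curves: Iterable[AmplificationCurve], path) -> None:
    """Long format: sample_id, reaction, cycle, fluorescence."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "reaction": c.reaction,
                    "cycle": c.cycles,
                    "fluorescence": c.fluorescence,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_curves_csv(path) -> list[AmplificationCurve]:
    df = pd.read_csv(path, dtype={"sample_id": str, "reaction": str}, float_precision="round_trip")
    curves = []
    for (sid, reaction), sub in df.groupby(["sample_id", "reaction"], sort=False):
        sub = sub.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                cycles=sub["cycle"].to_numpy(float),
                fluorescence=sub["fluorescence"].to_numpy(float),
                reaction=str(reaction),
                sample_id=str(sid),
            )
        )
    return curves


def read_cq_csv(path) -> pd.DataFrame:
    """Pre-called Cq values: sample_id, reaction, replicate, cq."""
    df = pd.read_csv(path, dtype={"sample_id": str, "reaction": str})
    required = {"sample_id", "reaction", "cq"}
    if not required.issubset(df.columns):
        raise DataError(f"Cq table must have columns {sorted(required)}")
    return df


# -- nuclei areas -------------------------------------------------------------

def write_nuclei_csv(samples: Iterable[NucleiSample], path) -> None:
    """Image-analysis export shape: sample_id, nucleus_id, area_um2."""
    rows = []
    for s in samples:
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "nucleus_id": np.arange(1, s.n + 1),
                    "area_um2": s.areas,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_nuclei_csv(path) -> list[NucleiSample]:
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    return [
        NucleiSample(sample_id=str(sid), areas=sub["area_um2"].to_numpy(float))
        for sid, sub in df.groupby("sample_id", sort=False)
    ]


# -- karyotype counts ---------------------------------------------------------

def write_karyotype_csv(counts: Iterable[KaryotypeCount], path, sample_id: str = "sample") -> None:
    pd.DataFrame(
        {
            "sample_id": sample_id,
            "timepoint": [c.timepoint for c in counts],
            "n_metaphases": [c.n_metaphases for c in counts],
            "n_tetraploid": [c.n_tetraploid for c in counts],
        }
    ).to_csv(path, index=False)


def read_karyotype_csv(path) -> list[KaryotypeCount]:
    df = pd.read_csv(path, dtype={"timepoint": str})
    return [
        KaryotypeCount(
            timepoint=str(r.timepoint),
            n_metaphases=int(r.n_metaphases),
            n_tetraploid=int(r.n_tetraploid),
        )
        for r in df.itertuples()
    ]


# -- sequences ----------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_cpg_sidecar(path) -> list[int]:
    """CpG coordinates (0-based, half-open) from a sidecar CSV with columns
    start, end; returns the cytosine positions (start of each CG)."""
    df = pd.read_csv(path)
    if "start" not in df.columns:
        raise DataError("CpG sidecar must have a 'start' column")
    return [int(v) for v in df["start"]]
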