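"""Bisulfite clone sequencing analysis of a CpG-rich repeat region.

Bisulfite treatment deaminates unmethylated cytosines to uracil (sequenced as
T) while 5-methylcytosine is protected.  Each cloned PCR molecule therefore
reports the methylation state of every CpG it covers: C = methylated,
T = unmethylated; a mismatch or deletion at the CpG (the region carries
polymorphic CpGs) is non-informative.  Retention of non-CpG cytosines flags
incomplete conversion.

The module calls per-molecule states, summarizes clones, partitions the
methylation variance into among- vs within-clone components (sum-of-squares
decomposition), and scores each CpG site by how well its binary state tracks
the molecule's overall methylation — the statistic used to choose
primer-binding CpGs for methylation-specific qPCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NoInformativeSites

__all__ = [
    "MethylationMatrix",
    "CloneSummary",
    "MoleculeCall",
    "call_states",
    "matrix_from_reads",
    "molecule_percent",
    "clone_summary",
    "variance_partition",
    "cpg_site_correlation",
    "compare_groups",
]

KARYOTYPE_LABELS = ("near_diploid", "near_tetraploid", "mixed", "unknown")

METHYLATED = 1.0
UNMETHYLATED = 0.0
# non-informative sites are stored as NaN


@dataclass
class MethylationMatrix:
    """Per-molecule x per-CpG methylation states for one clone.

    ``states`` is a molecules x sites float matrix with entries 1
    (methylated), 0 (unmethylated) or NaN (non-informative: polymorphic or
    deleted CpG).  ``conversion_ok`` marks molecules passing the bisulfite
    conversion filter.
    """

    clone_id: str
    states: np.ndarray
    site_labels: list[str] = field(default_factory=list)
    conversion_ok: np.ndarray = None
    molecule_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2:
            raise DataError("states must be a 2-d molecules x sites matrix")
        vals = self.states[np.isfinite(self.states)]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise DataError("states must be 0, 1 or NaN")
        n_mol, n_sites = self.states.shape
        if not self.site_labels:
            self.site_labels = [f"CpG{i + 1}" for i in range(n_sites)]
        if len(self.site_labels) != n_sites:
            raise DataError("site_labels length must match site count")
        if self.conversion_ok is None:
            self.conversion_ok = np.ones(n_mol, dtype=bool)
        self.conversion_ok = np.asarray(self.conversion_ok, dtype=bool)
        if not self.molecule_ids:
            self.molecule_ids = [f"{self.clone_id}_m{i + 1}" for i in range(n_mol)]

    @property
    def n_molecules(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]


@dataclass
class CloneSummary:
    """Clone-level methylation summary (percent scale)."""

    clone_id: str
    mean_meth: float
    sd_meth: float
    n_molecules: int
    karyotype_label: str = "unknown"
    single_molecule: bool = False

    def __post_init__(self) -> None:
        if self.karyotype_label not in KARYOTYPE_LABELS:
            raise DataError(f"unknown karyotype label {self.karyotype_label!r}")


@dataclass
class MoleculeCall:
    """States called from one aligned bisulfite read."""

    states: np.ndarray
    conversion_ok: bool
    non_cpg_retention: float


def call_states(
    read: str,
    reference: str,
    cpg_positions: Sequence[int],
    conversion_threshold: float = 0.05,
    min_identity: float = 0.7,
) -> MoleculeCall:
    """Call CpG methylation states from a bisulfite read aligned to the
    unconverted reference.

    At each CpG cytosine position: C -> methylated, T -> unmethylated, any
    other base or a gap -> non-informative (polymorphism/deletion).  The
    molecule fails the conversion filter when more than
    ``conversion_threshold`` of the reference's non-CpG cytosines are
    retained as C.  Reads of the reference length are compared directly;
    otherwise a global pairwise alignment anchors them.
    """
    read = read.upper()
    reference = reference.upper()
    for p in cpg_positions:
        if not (0 <= p < len(reference)) or reference[p] != "C":
            raise DataError(f"CpG position {p} is not a reference cytosine")

    if len(read) == len(reference):
        aligned = read
    else:
        aligned = _anchor_read(read, reference)

    # identity outside cytosine positions (bisulfite conversion touches only C)
    non_c = [i for i, b in enumerate(reference) if b != "C" and i < len(aligned)]
    if non_c:
        ident = np.mean([aligned[i] == reference[i] for i in non_c if aligned[i] != "-"] or [0.0])
        if ident < min_identity:
            raise DataError(f"unalignable read: identity {ident:.2f} below {min_identity}")

    cpg_set = set(cpg_positions)
    states = np.full(len(cpg_positions), np.nan)
    for k, p in enumerate(cpg_positions):
        base = aligned[p]
        if base == "C":
            states[k] = METHYLATED
        elif base == "T":
            states[k] = UNMETHYLATED
        # else: mismatch/deletion -> NaN

    non_cpg_c = [i for i, b in enumerate(reference) if b == "C" and i not in cpg_set]
    if non_cpg_c:
        retained = np.mean([aligned[i] == "C" for i in non_cpg_c])
    else:
        retained = 0.0
    return MoleculeCall(
        states=states,
        conversion_ok=bool(retained <= conversion_threshold),
        non_cpg_retention=float(retained),
    )


def _anchor_read(read: str, reference: str) -> str:
    """Project a read onto reference coordinates by global alignment,
    returning a reference-length string with '-' at deletions.  C/T are
    treated as equivalent (bisulfite space)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.open_end_gap_score = -2
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # align in bisulfite space (C collapsed to T) so conversion is not a mismatch
    aln = aligner.align(reference.replace("C", "T"), read.replace("U", "T").replace("C", "T"))[0]
    projected = ["-"] * len(reference)
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for off in range(r1 - r0):
            projected[r0 + off] = read[q0 + off]
    return "".join(projected)


def matrix_from_reads(
    clone_id: str,
    reads: Iterable[tuple[str, str]],
    reference: str,
    cpg_positions: Sequence[int],
    conversion_threshold: float = 0.05,
) -> MethylationMatrix:
    """Build a :class:`MethylationMatrix` from (molecule_id, sequence) reads."""
    ids, rows, conv = [], [], []
    for mol_id, seq in reads:
        call = call_states(seq, reference, cpg_positions, conversion_threshold)
        ids.append(mol_id)
        rows.append(call.states)
        conv.append(call.conversion_ok)
    if not rows:
        raise DataError(f"clone {clone_id}: no reads")
    return MethylationMatrix(
        clone_id=clone_id,
        states=np.vstack(rows),
        conversion_ok=np.array(conv),
        molecule_ids=ids,
    )


def molecule_percent(row: np.ndarray) -> float:
    """Percent methylation of one molecule: 100 * methylated / informative.

    Non-informative (NaN) sites are excluded from the denominator.
    """
    row = np.asarray(row, dtype=float)
    informative = np.isfinite(row)
    if not informative.any():
        raise NoInformativeSites("no informative sites")
    return float(100.0 * row[informative].sum() / informative.sum())


def _molecule_percents(matrix: MethylationMatrix, require_conversion: bool) -> np.ndarray:
    keep = matrix.conversion_ok if require_conversion else np.ones(matrix.n_molecules, bool)
    vals = []
    for i in np.flatnonzero(keep):
        row = matrix.states[i]
        if np.isfinite(row).any():
            vals.append(molecule_percent(row))
    if not vals:
        raise DataError(f"clone {matrix.clone_id}: no valid molecules after filtering")
    return np.asarray(vals)


def clone_summary(
    matrix: MethylationMatrix,
    karyotype_label: str = "unknown",
    require_conversion: bool = True,
) -> CloneSummary:
    """Mean and SD of per-molecule methylation over conversion-passing
    molecules; a single-molecule clone reports SD 0 with a flag."""
    vals = _molecule_percents(matrix, require_conversion)
    n = len(vals)
    return CloneSummary(
        clone_id=matrix.clone_id,
        mean_meth=float(np.mean(vals)),
        sd_meth=float(np.std(vals, ddof=1)) if n > 1 else 0.0,
        n_molecules=n,
        karyotype_label=karyotype_label,
        single_molecule=n == 1,
    )


def variance_partition(
    matrices: Sequence[MethylationMatrix], require_conversion: bool = True
) -> tuple[float, float]:
    """One-way sum-of-squares decomposition of per-molecule methylation by
    clone.

    Returns ``(pct_among_clones, pct_within_clones)`` — the percent of the
    total sum of squares explained by clone identity and by intra-clonal
    variability; they sum to 100.  A fully constant data set returns (0, 100).
    """
    if len(matrices) < 2:
        raise DataError("need at least 2 clones")
    groups = [_molecule_percents(m, require_conversion) for m in matrices]
    if max(len(g) for g in groups) < 2:
        # one molecule per clone: all variation is among clones
        allv = np.concatenate(groups)
        return (100.0, 0.0) if np.std(allv) > 0 else (0.0, 100.0)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    if ss_total == 0:
        return 0.0, 100.0
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    pct_among = 100.0 * ss_between / ss_total
    return pct_among, 100.0 - pct_among


def cpg_site_correlation(
    matrices: Sequence[MethylationMatrix],
    exclude_focal: bool = False,
    min_molecules: int = 3,
) -> pd.Series:
    """Per-CpG Pearson correlation between the site's binary state and the
    molecule's overall methylation percent, across all molecules where the
    site is informative.

    Sites with zero variance (always methylated or always unmethylated) or
    fewer than ``min_molecules`` informative molecules are *undefined* (NaN),
    not zero.  ``exclude_focal`` removes the focal site from the molecule's
    overall percent before correlating.
    """
    if not matrices:
        raise DataError("no matrices given")
    n_sites = matrices[0].n_sites
    labels = matrices[0].site_labels
    for m in matrices:
        if m.n_sites != n_sites:
            raise DataError("site count differs between matrices")
    states = np.vstack([m.states for m in matrices])

    out = np.full(n_sites, np.nan)
    for j in range(n_sites):
        informative = np.isfinite(states[:, j])
        xs, ys = [], []
        for i in np.flatnonzero(informative):
            row = states[i]
            if exclude_focal:
                row = np.delete(row, j)
            if not np.isfinite(row).any():
                continue
            xs.append(states[i, j])
            ys.append(molecule_percent(row))
        if len(xs) < min_molecules:
            continue
        xs, ys = np.asarray(xs), np.asarray(ys)
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue  # undefined, stays NaN
        out[j] = stats.pearsonr(xs, ys).statistic
    return pd.Series(out, index=labels, name="r")


def compare_groups(
    summaries: Sequence[CloneSummary],
    group_a: str = "near_tetraploid",
    group_b: str = "near_diploid",
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test on clone-level mean methylation
    between two karyotype groups (the clone, not the molecule, is the unit).

    Returns ``(t, df, p)``.
    """
    a = [s.mean_meth for s in summaries if s.karyotype_label == group_a]
    b = [s.mean_meth for s in summaries if s.karyotype_label == group_b]
    if len(a) < 2 or len(b) < 2:
        raise DataError("both groups need at least 2 clones")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), len(a) + len(b) - 2, float(res.pvalue)
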