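"""Alternative-splicing event enumeration and PSI analysis.

Events are derived from pairwise comparison of transcript exon chains within
a gene, yielding the seven classic local event types:

* SE — skipped exon; RI — retained intron; MX — mutually exclusive exons
  (strand-independent structure),
* A5 / A3 — alternative 5' (donor) / 3' (acceptor) splice site,
* AF / AL — alternative first / last exon,

where the strand decides which genomic boundary is the donor and which exon
is first in transcription.  The inclusion level PSI of an event in a sample
is the transcript-abundance ratio of the inclusion form over both forms.
Between-group differences (dPSI) are tested against an empirical null built
from within-group replicate differences, stratified by event expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import Annotation, Gene
from .stats import bh_adjust, hypergeom_tail

__all__ = [
    "SplicingEvent",
    "enumerate_events",
    "compute_psi",
    "test_dpsi",
    "overlap_test",
    "trend_test",
]

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")


@dataclass
class SplicingEvent:
    gene: str
    etype: str
    coords: tuple  # genomic coordinates of the variable region (0-based half-open)
    strand: str
    inclusion: set = field(default_factory=set)
    exclusion: set = field(default_factory=set)

    @property
    def event_id(self) -> str:
        pos = ":".join(str(c) for c in self.coords)
        return f"{self.gene};{self.etype}:{pos}:{self.strand}"


def _pair_events(gene: Gene, tx1: str, tx2: str):
    """Yield (etype, coords, inclusion_tx, exclusion_tx) for one transcript
    pair, genomically typed then strand-resolved."""
    e1 = gene.transcripts[tx1]
    e2 = gene.transcripts[tx2]
    strand = gene.strand
    minus = strand == "-"

    def flip(donor_side_type):  # A5<->A3, AF<->AL on the minus strand
        mapping = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF"}
        return mapping[donor_side_type] if minus else donor_side_type

    # --- SE: internal exon of one chain absent from the other, flanks shared
    for a, b, a_name, b_name in ((e1, e2, tx1, tx2), (e2, e1, tx2, tx1)):
        for i in range(1, len(a) - 1):
            exon = a[i]
            if exon in b:
                continue
            left_end = a[i - 1][1]
            right_start = a[i + 1][0]
            for j in range(len(b) - 1):
                if b[j][1] == left_end and b[j + 1][0] == right_start:
                    yield ("SE", (left_end, exon[0], exon[1], right_start), a_name, b_name)

    # --- RI: one chain's exon spans two adjacent exons of the other
    for a, b, a_name, b_name in ((e1, e2, tx1, tx2), (e2, e1, tx2, tx1)):
        for j in range(len(a) - 1):
            up, down = a[j], a[j + 1]
            for exon in b:
                if exon[0] == up[0] and exon[1] == down[1]:
                    # inclusion = the chain retaining the intron
                    yield ("RI", (up[0], up[1], down[0], down[1]), b_name, a_name)

    # --- A5/A3: exons sharing one boundary, common flanking junction
    for i, x1 in enumerate(e1):
        for j, x2 in enumerate(e2):
            if x1 == x2:
                continue
            if x1[0] == x2[0] and x1[1] != x2[1]:
                # variable genomic right boundary -> donor on "+", acceptor on "-"
                if i + 1 < len(e1) and j + 1 < len(e2) and e1[i + 1][0] == e2[j + 1][0]:
                    longer, shorter = (tx1, tx2) if x1[1] > x2[1] else (tx2, tx1)
                    coords = (x1[0], min(x1[1], x2[1]), max(x1[1], x2[1]), e1[i + 1][0])
                    yield (flip("A5"), coords, longer, shorter)
            elif x1[1] == x2[1] and x1[0] != x2[0]:
                if i > 0 and j > 0 and e1[i - 1][1] == e2[j - 1][1]:
                    longer, shorter = (tx1, tx2) if x1[0] < x2[0] else (tx2, tx1)
                    coords = (e1[i - 1][1], min(x1[0], x2[0]), max(x1[0], x2[0]), x1[1])
                    yield (flip("A3"), coords, longer, shorter)

    # --- MX: exclusive, non-overlapping internal exons between shared flanks
    for i in range(1, len(e1) - 1):
        if e1[i] in e2:
            continue
        for j in range(1, len(e2) - 1):
            if e2[j] in e1:
                continue
            a, b = e1[i], e2[j]
            if a[1] <= b[0] or b[1] <= a[0]:  # non-overlapping
                if e1[i - 1][1] == e2[j - 1][1] and e1[i + 1][0] == e2[j + 1][0]:
                    # inclusion = form whose exon is 5'-proximal in transcription
                    left_first = a[0] < b[0]
                    incl, excl = (tx1, tx2) if (left_first != minus) else (tx2, tx1)
                    lo, hi = (a, b) if a[0] < b[0] else (b, a)
                    coords = (e1[i - 1][1], lo[0], lo[1], hi[0], hi[1], e1[i + 1][0])
                    yield ("MX", coords, incl, excl)

    # --- AF/AL: distinct terminal exons joined to a common internal exon
    if len(e1) >= 2 and len(e2) >= 2:
        f1, f2 = e1[0], e2[0]
        if f1 != f2 and (f1[1] <= f2[0] or f2[1] <= f1[0]):
            if e1[1][0] == e2[1][0]:
                # genomic-left alternative start: AF on "+", AL on "-"
                lo, hi = (f1, f2) if f1[0] < f2[0] else (f2, f1)
                # inclusion = form whose terminal exon is transcription-proximal
                incl, excl = (tx1, tx2) if ((f1[0] < f2[0]) != minus) else (tx2, tx1)
                coords = (lo[0], lo[1], hi[0], hi[1], e1[1][0])
                yield (flip("AF"), coords, incl, excl)
        l1, l2 = e1[-1], e2[-1]
        if l1 != l2 and (l1[1] <= l2[0] or l2[1] <= l1[0]):
            if e1[-2][1] == e2[-2][1]:
                lo, hi = (l1, l2) if l1[0] < l2[0] else (l2, l1)
                incl, excl = (tx1, tx2) if ((l1[0] > l2[0]) != minus) else (tx2, tx1)
                coords = (e1[-2][1], lo[0], lo[1], hi[0], hi[1])
                yield (flip("AL"), coords, incl, excl)


def enumerate_events(annotation: Annotation) -> list[SplicingEvent]:
    """Enumerate local splicing events from all transcript pairs per gene.

    Events with identical (gene, type, coordinates) found in several pairs
    are merged, unioning their transcript sets.
    """
    merged: dict[tuple, SplicingEvent] = {}
    for gene in annotation.genes.values():
        tx_ids = sorted(gene.transcripts)
        for i, tx1 in enumerate(tx_ids):
            for tx2 in tx_ids[i + 1 :]:
                for etype, coords, incl, excl in _pair_events(gene, tx1, tx2):
                    key = (gene.gene_id, etype, coords)
                    ev = merged.get(key)
                    if ev is None:
                        ev = SplicingEvent(gene.gene_id, etype, coords, gene.strand)
                        merged[key] = ev
                    ev.inclusion.add(incl)
                    ev.exclusion.add(excl)
    events = [ev for ev in merged.values() if not (ev.inclusion & ev.exclusion)]
    return sorted(events, key=lambda e: e.event_id)


def compute_psi(
    events: list[SplicingEvent],
    tpm: pd.DataFrame,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Per-sample PSI: inclusion TPM / (inclusion + exclusion TPM).

    PSI is missing (NaN) when the combined form abundance is below ``floor``.
    """
    rows = {}
    for ev in events:
        incl = tpm.reindex(sorted(ev.inclusion)).fillna(0.0).sum(axis=0)
        excl = tpm.reindex(sorted(ev.exclusion)).fillna(0.0).sum(axis=0)
        denom = incl + excl
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(denom >= floor, incl / denom, np.nan)
        rows[ev.event_id] = psi
    return pd.DataFrame.from_dict(rows, orient="index", columns=tpm.columns)


def event_expression(events: list[SplicingEvent], tpm: pd.DataFrame) -> pd.Series:
    """Mean log10 combined-form TPM per event, used for null stratification."""
    vals = {}
    for ev in events:
        total = tpm.reindex(sorted(ev.inclusion | ev.exclusion)).fillna(0.0).sum(axis=0)
        vals[ev.event_id] = float(np.log10(total.mean() + 1.0))
    return pd.Series(vals)


def test_dpsi(
    psi: pd.DataFrame,
    expression: pd.Series,
    group_of: pd.Series,
    contrast: tuple,
    n_bins: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """dPSI between two groups with an empirical, expression-stratified null.

    dPSI = mean PSI(group2) - mean PSI(group1).  The null pool per expression
    bin collects |PSI_i - PSI_j| over all within-group replicate pairs of all
    events in the bin; p = (1 + #null >= |dPSI|) / (1 + #null).  BH across
    events.  Events with < 2 non-missing replicates in either group are
    dropped; an empty bin falls back to the global null.
    """
    g2, g1 = contrast
    cols1 = group_of.index[group_of == g1]
    cols2 = group_of.index[group_of == g2]
    a = psi[cols1].to_numpy(dtype=float)
    b = psi[cols2].to_numpy(dtype=float)
    n1 = np.sum(np.isfinite(a), axis=1)
    n2 = np.sum(np.isfinite(b), axis=1)
    testable = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore"):
        dpsi = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)

    expr = expression.reindex(psi.index).to_numpy(dtype=float)
    ranks = pd.Series(expr).rank(method="first").to_numpy()
    bins = np.minimum(((ranks - 1) / len(ranks) * n_bins).astype(int), n_bins - 1)

    # within-group replicate |differences| per event
    def pair_diffs(mat: np.ndarray) -> list[np.ndarray]:
        out = []
        for row in mat:
            v = row[np.isfinite(row)]
            if v.size < 2:
                out.append(np.empty(0))
            else:
                d = np.abs(v[:, None] - v[None, :])
                out.append(d[np.triu_indices(v.size, k=1)])
        return out

    diffs = [np.concatenate([x, y]) for x, y in zip(pair_diffs(a), pair_diffs(b))]
    null_by_bin = {}
    for bi in range(n_bins):
        pool = [d for d, bb, t in zip(diffs, bins, testable) if bb == bi and t]
        null_by_bin[bi] = np.concatenate(pool) if pool else np.empty(0)
    global_null = np.concatenate([d for d, t in zip(diffs, testable) if t] or [np.empty(0)])

    p = np.full(len(psi), np.nan)
    for i in range(len(psi)):
        if not testable[i]:
            continue
        null = null_by_bin[bins[i]]
        if null.size == 0:
            null = global_null
        p[i] = (1.0 + np.sum(null >= abs(dpsi[i]))) / (1.0 + null.size)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "event_id": psi.index,
            "contrast": f"{g2}v{g1}",
            "dpsi": dpsi,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    ).set_index("event_id")


def overlap_test(n_a: int, n_b: int, n_both: int, universe: int):
    """One-sided Fisher test for the overlap of two event sets.

    Returns (expected overlap under independence, upper-tail p).  Computed in
    log space; for astronomically small tails use
    ``hypergeom_tail(..., log=True)`` via the returned log10 companion.
    """
    expected = n_a * n_b / universe
    logp = hypergeom_tail(n_both, universe, n_a, n_b, log=True)
    return expected, float(np.exp(logp)), logp / np.log(10.0)


def trend_test(counts) -> tuple[float, float]:
    """Pearson chi-square of event counts across ordered comparisons against
    the uniform expectation."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    if counts.sum() <= 0:
        raise ValueError("all counts are zero")
    stat, p = sps.chisquare(counts)
    return float(stat), float(p)
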