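"""Alternative polyadenylation (APA) quantification from terminal fragments.

Each transcript contributes a terminal fragment — its final two exons in
transcription direction (the single exon if monoexonic) — carrying the
transcript's 3'-end coordinate.  Fragments whose 3' ends lie within a fixed
window (default 25 nt, inclusive, single-linkage) are grouped into one APA
site.  Sites are ordered proximal -> distal along transcription and carry
positional weights 0 .. 1; a gene's psi in a sample is the weight-averaged
relative usage of its sites, so psi = 0 means exclusive proximal usage and
psi = 1 exclusive distal usage.  Between-group psi differences are tested
with a Welch t-test and BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import Annotation, Gene
from .stats import bh_adjust

__all__ = [
    "TerminalFragment",
    "ApaSite",
    "ApaGene",
    "terminal_fragments",
    "group_apa_sites",
    "compute_gene_psi",
    "test_apa",
]

DEFAULT_WINDOW = 25
DEFAULT_FLOOR = 1.0


@dataclass(frozen=True)
class TerminalFragment:
    transcript: str
    gene: str
    strand: str
    exons: tuple  # final two exons (or one), genomic order
    three_prime: int  # 3'-end coordinate (0-based half-open convention)


@dataclass
class ApaSite:
    index: int          # 0 = most proximal
    weight: float       # index / (n_sites - 1)
    transcripts: list
    three_prime: int    # representative (mean) 3' end


@dataclass
class ApaGene:
    gene: str
    strand: str
    sites: list  # ordered proximal -> distal

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def terminal_fragments(annotation: Annotation) -> list[TerminalFragment]:
    """The 3'-most two exons of each transcript, in transcription direction."""
    out = []
    for gene in annotation.genes.values():
        for tx_id, exons in gene.transcripts.items():
            if gene.strand == "+":
                frag = tuple(exons[-2:])
                three_prime = exons[-1][1]
            else:
                frag = tuple(exons[:2])
                three_prime = exons[0][0]
            out.append(TerminalFragment(tx_id, gene.gene_id, gene.strand, frag, three_prime))
    return out


def group_apa_sites(
    fragments: list[TerminalFragment],
    window: int = DEFAULT_WINDOW,
) -> ApaGene:
    """Single-linkage grouping of one gene's fragment 3' ends.

    Ends within ``window`` nt of each other (inclusive) chain into one site.
    Sites are ordered proximal -> distal in transcription direction; weights
    run from 0 (most proximal) to 1 (most distal).
    """
    if not fragments:
        raise ValueError("no fragments")
    strands = {f.strand for f in fragments}
    genes = {f.gene for f in fragments}
    if len(strands) != 1 or len(genes) != 1:
        raise ValueError("fragments must come from a single gene and strand")
    strand = strands.pop()
    ordered = sorted(fragments, key=lambda f: f.three_prime)
    clusters: list[list[TerminalFragment]] = [[ordered[0]]]
    for frag in ordered[1:]:
        if frag.three_prime - clusters[-1][-1].three_prime <= window:
            clusters[-1].append(frag)
        else:
            clusters.append([frag])
    if strand == "-":  # proximal = genomically rightmost on the minus strand
        clusters = clusters[::-1]
    n = len(clusters)
    sites = [
        ApaSite(
            index=m,
            weight=(m / (n - 1)) if n > 1 else 0.0,
            transcripts=sorted(f.transcript for f in cl),
            three_prime=int(round(np.mean([f.three_prime for f in cl]))),
        )
        for m, cl in enumerate(clusters)
    ]
    return ApaGene(gene=genes.pop() if genes else fragments[0].gene, strand=strand, sites=sites)


def build_apa_genes(annotation: Annotation, window: int = DEFAULT_WINDOW) -> dict[str, ApaGene]:
    """Group fragments per gene; includes single-site genes (excluded from
    testing downstream)."""
    frags: dict[str, list[TerminalFragment]] = {}
    for f in terminal_fragments(annotation):
        frags.setdefault(f.gene, []).append(f)
    return {g: group_apa_sites(fl, window) for g, fl in frags.items()}


def compute_gene_psi(
    apa_gene: ApaGene,
    tpm: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
) -> pd.Series:
    """Positional-weighted site usage per sample.

    psi[s] = sum_m w_m * f_m[s] with f_m the site's share of the gene's
    terminal TPM; missing when that total is below ``floor``.
    """
    site_tpm = np.vstack(
        [tpm.reindex(site.transcripts).fillna(0.0).sum(axis=0).to_numpy() for site in apa_gene.sites]
    )
    total = site_tpm.sum(axis=0)
    weights = np.array([site.weight for site in apa_gene.sites])
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total >= floor, (weights[:, None] * site_tpm).sum(axis=0) / total, np.nan)
    return pd.Series(psi, index=tpm.columns, name=apa_gene.gene)


def test_apa(
    psi: pd.DataFrame,
    group_of: pd.Series,
    contrast: tuple,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test of per-gene psi between two groups, BH-corrected.

    Degenerate zero-variance cases: equal means -> p = 1, unequal -> p -> 0.
    Genes with < 2 non-missing psi in either group are dropped (NaN p).
    """
    g2, g1 = contrast
    a = psi[group_of.index[group_of == g1]].to_numpy(dtype=float)
    b = psi[group_of.index[group_of == g2]].to_numpy(dtype=float)
    n1 = np.sum(np.isfinite(a), axis=1)
    n2 = np.sum(np.isfinite(b), axis=1)
    with np.errstate(invalid="ignore"):
        dpsi = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    p = np.full(len(psi), np.nan)
    for i in range(len(psi)):
        if n1[i] < 2 or n2[i] < 2:
            continue
        x, y = a[i][np.isfinite(a[i])], b[i][np.isfinite(b[i])]
        # variance identically zero up to float cancellation noise
        if x.var(ddof=1) <= 1e-20 and y.var(ddof=1) <= 1e-20:
            p[i] = 1.0 if abs(x.mean() - y.mean()) <= 1e-12 else 0.0
        else:
            p[i] = float(sps.ttest_ind(y, x, equal_var=False).pvalue)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": psi.index,
            "contrast": f"{g2}v{g1}",
            "dpsi": dpsi,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    ).set_index("gene")
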