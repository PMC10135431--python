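"""Synthetic paired transcriptome/translatome data with planted ground truth.

The generator emulates the design of a four-age-group polysome-profiling
study: 5/6/4/5 subjects at 3/6/12/20 months, each contributing one total-RNA
and one polysome library, processed in batches.  Counts follow a negative
binomial law with gene-wise dispersion; library depth is anchored at the
8e6-read operating point of the abundance filter; batch effects are additive
gene-wise log2 offsets; matched fractions of a subject share a subject-level
random effect.  Planted regulatory modes follow translatome semantics:
``translation`` genes shift polysome means only, ``buffering`` genes shift
total means only, ``abundance`` genes shift both equally.

Transcript-level TPM tables are generated separately from a toy annotation
whose gene models realize each of the seven local splicing event types and
configurable alternative-polyadenylation site structures, with planted PSI
and psi values recoverable by the splicing and APA modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, Gene

__all__ = [
    "StudyDesign",
    "TruthTable",
    "CountExperiment",
    "build_toy_annotation",
    "simulate_experiment",
    "simulate_transcript_tpm",
    "simulate_mode_matrices",
]

#: nominal sequencing depth; also the anchor of the abundance filter
NOMINAL_LIBRARY = 8e6

#: sd of log2 library-depth variation between samples
DEPTH_LOG2_SD = 0.15

#: sd of the subject-level log2 random effect shared by a subject's two
#: fractions; the coupling it induces between total and polysome samples is
#: what makes translation effects separable from abundance effects
SUBJECT_LOG2_SD = 0.2

#: fraction of the per-sample log2 noise variance that is subject-shared in
#: the paired-fraction simulation: both libraries of a subject derive from
#: one tissue homogenate, so biological subject-to-subject variation (shared)
#: dominates the fraction-specific residual
MODE_SIM_COUPLING = 0.9

#: log-normal spread (sd of log) of gene-wise dispersions around the
#: configured value
DISPERSION_LOG_SD = 0.5

#: log2-offset sd injected into designated outlier samples
OUTLIER_LOG2_SD = 2.0

TRAJECTORY_SHAPES = {
    "up": (0.0, 1 / 3, 2 / 3, 1.0),
    "down": (1.0, 2 / 3, 1 / 3, 0.0),
    "peak": (0.0, 0.5, 1.0, 0.0),
    "V": (1.0, 0.0, 0.0, 1.0),
    "flat": (0.0, 0.0, 0.0, 0.0),
}

PAPER_GROUP_SIZES = {3: 5, 6: 6, 12: 4, 20: 5}


@dataclass
class StudyDesign:
    """Subjects per age group, batch labels, and the paired-fraction layout."""

    group_sizes: dict = field(default_factory=lambda: dict(PAPER_GROUP_SIZES))
    n_batches: int = 2

    def __post_init__(self):
        ages = list(self.group_sizes)
        if ages != sorted(ages):
            raise ValueError("ages must be strictly increasing")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every age group needs >= 2 subjects")

    @property
    def ages(self) -> tuple:
        return tuple(self.group_sizes)

    def subjects(self) -> pd.DataFrame:
        rows = []
        i = 0
        for age, n in self.group_sizes.items():
            for _ in range(n):
                rows.append(
                    {"subject_id": f"m{i:02d}", "age_months": age, "batch": f"b{i % self.n_batches}"}
                )
                i += 1
        return pd.DataFrame(rows)

    def samples(self) -> pd.DataFrame:
        """One total and one polysome sample per subject."""
        rows = []
        for _, subj in self.subjects().iterrows():
            for fraction, tag in (("total", "T"), ("polysome", "P")):
                rows.append(
                    {
                        "sample_id": f"{subj.subject_id}_{tag}",
                        "subject_id": subj.subject_id,
                        "age_months": subj.age_months,
                        "fraction": fraction,
                        "batch": subj.batch,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id", drop=False)


@dataclass
class CountExperiment:
    counts: pd.DataFrame     # genes x samples, integer
    samples: pd.DataFrame    # sample metadata

    def fraction(self, name: str) -> pd.DataFrame:
        cols = self.samples.index[self.samples["fraction"] == name]
        return self.counts[cols]


@dataclass
class TruthTable:
    """Planted ground truth for recovery testing."""

    modes: pd.Series                 # gene -> mode label ("none" for null genes)
    trajectory: pd.Series            # gene -> shape class
    offsets_total: pd.DataFrame      # gene x age log2 offsets (total fraction)
    offsets_polysome: pd.DataFrame   # gene x age log2 offsets (polysome)
    psi: pd.DataFrame | None = None      # AS gene x age planted PSI
    apa_psi: pd.DataFrame | None = None  # APA gene x age planted psi

    def mode_for_contrast(self, contrast, min_delta: float = 1e-9) -> pd.Series:
        """Per-gene true mode for one (later, earlier) age contrast: the
        planted mode where the offset actually moves, else none."""
        b, a = int(contrast[0]), int(contrast[1])
        d_tot = (self.offsets_total[b] - self.offsets_total[a]).abs()
        d_pol = (self.offsets_polysome[b] - self.offsets_polysome[a]).abs()
        moved = (d_tot > min_delta) | (d_pol > min_delta)
        return self.modes.where(moved, "none")


# ---------------------------------------------------------------------------
# toy annotation


def _event_gene(etype: str, origin: int, strand: str) -> tuple[list, list]:
    """Canonical two-transcript gene model realizing one event type.

    Returns the two alternative exon chains in genomic 0-based half-open
    coordinates shifted by ``origin``.  For the strand-polarized types
    (A5/A3/AF/AL) the genomic pattern is mirrored on the minus strand so the
    *transcriptional* event type is the one requested.
    """
    o = origin
    if etype == "SE":
        a = [(o + 100, o + 200), (o + 300, o + 400), (o + 500, o + 600)]
        b = [(o + 100, o + 200), (o + 500, o + 600)]
    elif etype == "RI":
        a = [(o + 100, o + 400)]
        b = [(o + 100, o + 200), (o + 300, o + 400)]
    elif etype == "MX":
        a = [(o + 100, o + 200), (o + 300, o + 400), (o + 700, o + 800)]
        b = [(o + 100, o + 200), (o + 500, o + 600), (o + 700, o + 800)]
    elif (etype, strand) in (("A5", "+"), ("A3", "-")):
        # variable donor-side (genomic right) exon boundary, common downstream
        a = [(o + 100, o + 250), (o + 400, o + 500)]
        b = [(o + 100, o + 200), (o + 400, o + 500)]
    elif (etype, strand) in (("A3", "+"), ("A5", "-")):
        # variable acceptor-side (genomic left) boundary, common upstream
        a = [(o + 100, o + 200), (o + 300, o + 500)]
        b = [(o + 100, o + 200), (o + 350, o + 500)]
    elif (etype, strand) in (("AF", "+"), ("AL", "-")):
        # distinct genomic-leftmost exons joined to a common downstream exon
        a = [(o + 100, o + 200), (o + 500, o + 600)]
        b = [(o + 300, o + 400), (o + 500, o + 600)]
    elif (etype, strand) in (("AL", "+"), ("AF", "-")):
        a = [(o + 100, o + 200), (o + 300, o + 400)]
        b = [(o + 100, o + 200), (o + 500, o + 600)]
    else:
        raise ValueError(f"unknown event type {etype!r}")
    return a, b


def build_toy_annotation(
    n_genes_per_event_type: int = 1,
    n_apa_genes: int = 1,
    seed: int = 0,
) -> tuple[Annotation, pd.DataFrame]:
    """Gene models realizing each of the seven event types plus APA genes.

    Returns the annotation and an event registry DataFrame (gene, type,
    inclusion/exclusion transcript ids) recording what was planted.  Strands
    alternate across genes so both are represented.  APA genes carry two
    transcripts whose terminal 3' ends differ by more than 25 nt.
    """
    if n_genes_per_event_type < 1 or n_apa_genes < 1:
        raise ValueError("counts must be >= 1")
    from .splicing import EVENT_TYPES, enumerate_events

    ann = Annotation()
    registry = []
    origin = 10_000
    gene_idx = 0
    for etype in EVENT_TYPES:
        for i in range(n_genes_per_event_type):
            strand = "+" if gene_idx % 2 == 0 else "-"
            gene_id = f"g_{etype}_{i}"
            gene = Gene(gene_id, "chr1", strand)
            form_a, form_b = _event_gene(etype, origin, strand)
            gene.add_transcript(f"{gene_id}.t1", form_a)
            gene.add_transcript(f"{gene_id}.t2", form_b)
            # label inclusion/exclusion by the event the model realizes
            single = Annotation(genes={gene_id: gene})
            events = enumerate_events(single)
            if len(events) != 1 or events[0].etype != etype:
                raise AssertionError(
                    f"toy model for {etype} ({strand}) realizes "
                    f"{[e.etype for e in events]} instead"
                )
            ev = events[0]
            ann.genes[gene_id] = gene
            registry.append(
                {
                    "gene": gene_id,
                    "etype": etype,
                    "inclusion": sorted(ev.inclusion)[0],
                    "exclusion": sorted(ev.exclusion)[0],
                }
            )
            origin += 2_000
            gene_idx += 1
    for i in range(n_apa_genes):
        strand = "+" if gene_idx % 2 == 0 else "-"
        gene_id = f"g_APA_{i}"
        gene = Gene(gene_id, "chr2", strand)
        o = origin
        # two transcripts whose terminal 3' ends differ by > 25 nt
        if strand == "+":
            gene.add_transcript(f"{gene_id}.prox", [(o + 100, o + 200), (o + 300, o + 400)])
            gene.add_transcript(f"{gene_id}.dist", [(o + 100, o + 200), (o + 300, o + 700)])
        else:  # 3' end is the genomic-left coordinate
            gene.add_transcript(f"{gene_id}.prox", [(o + 300, o + 400), (o + 500, o + 600)])
            gene.add_transcript(f"{gene_id}.dist", [(o + 100, o + 400), (o + 500, o + 600)])
        ann.genes[gene_id] = gene
        registry.append(
            {
                "gene": gene_id,
                "etype": "APA",
                "inclusion": f"{gene_id}.dist",
                "exclusion": f"{gene_id}.prox",
            }
        )
        origin += 2_000
        gene_idx += 1
    _ = seed  # gene-model layout is deterministic; seed kept for interface stability
    return ann, pd.DataFrame(registry).set_index("gene")


# ---------------------------------------------------------------------------
# count simulation


def _negative_binomial(rng, mean, dispersion):
    """NB draws with variance mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(
    design: StudyDesign,
    n_genes: int = 2000,
    mode_config: dict | None = None,
    dispersion: float = 0.05,
    base_mean: float | None = None,
    batch_effect_sd: float = 0.2,
    outlier_samples: tuple = (),
    seed: int = 0,
) -> tuple[CountExperiment, TruthTable]:
    """Negative-binomial paired count matrices with planted regulatory modes.

    ``mode_config`` maps mode -> (gene count, log2 effect size); each planted
    gene receives a random non-flat trajectory shape scaled by the effect.
    ``translation`` offsets apply to polysome samples only, ``buffering`` to
    total only, ``abundance`` to both.  Samples named in ``outlier_samples``
    receive independent gene-wise mean perturbations large enough to depress
    their average correlation to the rest of their fraction.
    """
    if len(design.group_sizes) < 2:
        raise ValueError("degenerate design: need at least two age groups")
    mode_config = dict(mode_config or {})
    n_planted = sum(c for c, _ in mode_config.values())
    if n_planted > n_genes:
        raise ValueError("mode counts exceed n_genes")
    rng = np.random.default_rng(seed)
    samples = design.samples()
    ages = list(design.ages)
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")

    if base_mean is None:
        base_mean = NOMINAL_LIBRARY / n_genes
    gene_mean = base_mean * rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    gene_mean *= n_genes * base_mean / gene_mean.sum()  # keep the depth anchor
    phi = dispersion * rng.lognormal(0.0, DISPERSION_LOG_SD, size=n_genes)

    # planted truth
    modes = pd.Series("none", index=genes)
    trajectory = pd.Series("flat", index=genes)
    off_t = pd.DataFrame(0.0, index=genes, columns=ages)
    off_p = pd.DataFrame(0.0, index=genes, columns=ages)
    # monotone shapes only when fewer than 4 ages (peak/V need the full span)
    shape_names = (
        [s for s in TRAJECTORY_SHAPES if s != "flat"]
        if len(ages) >= 4
        else ["up", "down"]
    )
    grid = np.linspace(0.0, 1.0, len(ages))
    template_grid = np.linspace(0.0, 1.0, 4)

    def _shape_offsets(shape):
        vals = np.interp(grid, template_grid, TRAJECTORY_SHAPES[shape])
        peak = np.abs(vals).max()
        return vals / peak  # effect size = largest |offset| across ages

    cursor = 0
    for mode, (count, effect) in mode_config.items():
        for g in range(cursor, cursor + count):
            gene = genes[g]
            shape = shape_names[int(rng.integers(len(shape_names)))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            offs = sign * effect * _shape_offsets(shape)
            modes[gene] = mode
            trajectory[gene] = shape
            if mode in ("abundance", "buffering"):
                off_t.loc[gene] = offs
            if mode in ("abundance", "translation"):
                off_p.loc[gene] = offs
        cursor += count

    subj = design.subjects()
    subject_effect = {
        s: rng.normal(0.0, SUBJECT_LOG2_SD, size=n_genes) for s in subj["subject_id"]
    }
    batch_offset = {
        b: rng.normal(0.0, batch_effect_sd, size=n_genes)
        for b in subj["batch"].unique()
    }

    counts = {}
    for _, row in samples.iterrows():
        depth = 2.0 ** rng.normal(0.0, DEPTH_LOG2_SD)
        offsets = (off_t if row.fraction == "total" else off_p)[row.age_months].to_numpy()
        log2_shift = offsets + batch_offset[row.batch] + subject_effect[row.subject_id]
        if row.sample_id in set(outlier_samples):
            log2_shift = log2_shift + rng.normal(0.0, OUTLIER_LOG2_SD, size=n_genes)
        mu = gene_mean * depth * 2.0**log2_shift
        counts[row.sample_id] = _negative_binomial(rng, mu, phi)
    counts = pd.DataFrame(counts, index=genes)[samples.index]
    truth = TruthTable(
        modes=modes, trajectory=trajectory, offsets_total=off_t, offsets_polysome=off_p
    )
    return CountExperiment(counts=counts, samples=samples), truth


# ---------------------------------------------------------------------------
# transcript TPM simulation


def _logit_noise(rng, psi: float, noise_sd: float) -> float:
    """PSI-scale noise of sd ~ noise_sd, applied on the logit scale and
    clipped to [0, 1].  Exact 0/1 values stay exact."""
    if noise_sd == 0 or psi <= 0.0 or psi >= 1.0:
        return float(np.clip(psi, 0.0, 1.0))
    scale = noise_sd / (psi * (1.0 - psi))  # delta-method match of the sd
    z = np.log(psi / (1.0 - psi)) + rng.normal(0.0, scale)
    return float(1.0 / (1.0 + np.exp(-z)))


def simulate_transcript_tpm(
    annotation: Annotation,
    design: StudyDesign,
    psi_truth: dict | None = None,
    apa_truth: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    registry: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Transcript TPM table realizing planted PSI / APA psi values.

    ``psi_truth`` maps an AS gene id to its per-age PSI (dict age -> value in
    [0, 1]); ``apa_truth`` maps an APA gene id to per-age distal-usage psi.
    The inclusion/exclusion transcript split comes from ``registry`` (the
    second return of :func:`build_toy_annotation`).  Per-sample TPM columns
    sum to 1e6.
    """
    rng = np.random.default_rng(seed)
    psi_truth = psi_truth or {}
    apa_truth = apa_truth or {}
    for table, label in ((psi_truth, "PSI"), (apa_truth, "psi")):
        for gene, per_age in table.items():
            if gene not in annotation.genes:
                raise KeyError(f"{label} truth references unknown gene {gene!r}")
            for v in per_age.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"planted {label} outside [0,1] for {gene!r}")
    samples = design.samples()
    tx_ids = annotation.transcripts()
    gene_abundance = {
        g: rng.lognormal(np.log(50.0), 1.0) for g in annotation.genes
    }
    cols = {}
    for _, row in samples.iterrows():
        vals = pd.Series(0.0, index=pd.Index(tx_ids, name="transcript_id"))
        for gene_id, gene in annotation.genes.items():
            a = gene_abundance[gene_id]
            planted = psi_truth.get(gene_id, apa_truth.get(gene_id))
            if planted is not None and registry is not None and gene_id in registry.index:
                psi = _logit_noise(rng, planted[row.age_months], noise_sd)
                inc = registry.loc[gene_id, "inclusion"]
                exc = registry.loc[gene_id, "exclusion"]
                vals[inc] = a * psi
                vals[exc] = a * (1.0 - psi)
            else:
                share = a / len(gene.transcripts)
                for tx in gene.transcripts:
                    vals[tx] = share
        cols[row.sample_id] = vals
    tpm = pd.DataFrame(cols)
    return tpm / tpm.sum(axis=0) * 1e6


# ---------------------------------------------------------------------------
# direct log2-scale simulation for regulatory-mode recovery


def simulate_mode_matrices(
    n_genes: int,
    mode_config: dict,
    group_sizes: tuple = (6, 5),
    group_ages: tuple = (6, 20),
    noise_sd: float = 0.25,
    coupling: float = MODE_SIM_COUPLING,
    seed: int = 0,
):
    """Two-group paired log2-expression matrices with planted modes.

    A lighter-weight companion to :func:`simulate_experiment` for testing the
    regulatory-mode classifier directly on the log2 scale: per gene,
    total = mu + u_subject + dT*I(group2) + noise and polysome = mu +
    u_subject + dP*I(group2) + noise, with (dT, dP) = (e, e), (0, e), (e, 0)
    for abundance / translation / buffering and random sign per gene.

    ``noise_sd`` is the total per-sample log2 sd; ``coupling`` is the share
    of its variance carried by the subject-level effect u (shared between a
    subject's two fractions), the remainder being fraction-specific noise.

    Returns (total, polysome, samples, truth_modes).
    """
    rng = np.random.default_rng(seed)
    subject_sd = noise_sd * np.sqrt(coupling)
    resid_sd = noise_sd * np.sqrt(1.0 - coupling)
    n_planted = sum(c for c, _ in mode_config.values())
    if n_planted > n_genes:
        raise ValueError("mode counts exceed n_genes")
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    truth = pd.Series("none", index=genes)
    d_t = np.zeros(n_genes)
    d_p = np.zeros(n_genes)
    cursor = 0
    for mode, (count, effect) in mode_config.items():
        sl = slice(cursor, cursor + count)
        signs = np.where(rng.random(count) < 0.5, 1.0, -1.0)
        if mode in ("abundance", "buffering"):
            d_t[sl] = signs * effect
        if mode in ("abundance", "translation"):
            d_p[sl] = signs * effect
        truth.iloc[sl] = mode
        cursor += count

    rows = []
    subj_ids = []
    for age, n in zip(group_ages, group_sizes):
        for i in range(n):
            sid = f"m{age}_{i}"
            subj_ids.append((sid, age))
            for fraction, tag in (("total", "T"), ("polysome", "P")):
                rows.append(
                    {
                        "sample_id": f"{sid}_{tag}",
                        "subject_id": sid,
                        "age_months": age,
                        "fraction": fraction,
                        "batch": "b0",
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)

    mu = rng.normal(5.0, 2.0, size=n_genes)
    total_cols, poly_cols = {}, {}
    for sid, age in subj_ids:
        u = rng.normal(0.0, subject_sd, size=n_genes)
        ind = 1.0 if age == group_ages[1] else 0.0
        total_cols[f"{sid}_T"] = mu + u + d_t * ind + rng.normal(0, resid_sd, n_genes)
        poly_cols[f"{sid}_P"] = mu + u + d_p * ind + rng.normal(0, resid_sd, n_genes)
    total = pd.DataFrame(total_cols, index=genes)
    poly = pd.DataFrame(poly_cols, index=genes)
    return total, poly, samples, truth
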