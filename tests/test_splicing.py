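"""Splicing event enumeration, PSI, and the dPSI / overlap / trend tests."""

import numpy as np
import pandas as pd
import pytest

from ribolens import splicing
from ribolens.annotation import Annotation, Gene
from ribolens.splicing import (
    EVENT_TYPES,
    compute_psi,
    enumerate_events,
    overlap_test,
    trend_test,
)


def _gene(strand, chains, gene_id="g", chrom="chr1"):
    gene = Gene(gene_id, chrom, strand)
    for i, exons in enumerate(chains):
        gene.add_transcript(f"{gene_id}.t{i + 1}", exons)
    return Annotation(genes={gene_id: gene})


def _reflect(ann: Annotation, span=100_000) -> Annotation:
    """Mirror all coordinates and flip strands."""
    out = Annotation()
    for gid, gene in ann.genes.items():
        flipped = Gene(gid, gene.chrom, "-" if gene.strand == "+" else "+")
        for tx, exons in gene.transcripts.items():
            flipped.add_transcript(tx, [(span - e, span - s) for s, e in exons])
        out.genes[gid] = flipped
    return out


class TestEnumeration:
    def test_canonical_skipped_exon(self):
        ann = _gene(
            "+",
            [
                [(100, 200), (300, 400), (500, 600)],
                [(100, 200), (500, 600)],
            ],
        )
        events = enumerate_events(ann)
        assert len(events) == 1
        ev = events[0]
        assert ev.etype == "SE"
        assert ev.inclusion == {"g.t1"} and ev.exclusion == {"g.t2"}

    def test_minus_strand_a5_is_not_a3(self):
        # variable genomic-left boundary with common upstream exon: A3 on "+",
        # hence A5 when the same structure sits on the minus strand
        chains = [
            [(100, 200), (300, 500)],
            [(100, 200), (350, 500)],
        ]
        plus = enumerate_events(_gene("+", chains))
        minus = enumerate_events(_gene("-", chains))
        assert [e.etype for e in plus] == ["A3"]
        assert [e.etype for e in minus] == ["A5"]

    def test_single_transcript_gene_has_no_events(self):
        ann = _gene("+", [[(100, 200), (300, 400)]])
        assert enumerate_events(ann) == []

    def test_toy_annotation_round_trip(self, toy_annotation):
        ann, registry = toy_annotation
        events = enumerate_events(ann)
        by_gene = {}
        for ev in events:
            by_gene.setdefault(ev.gene, []).append(ev)
        for gene, row in registry.iterrows():
            if row["etype"] == "APA":
                continue
            assert [e.etype for e in by_gene[gene]] == [row["etype"]]
            ev = by_gene[gene][0]
            assert ev.inclusion == {row["inclusion"]}
            assert ev.exclusion == {row["exclusion"]}

    def test_strand_reflection_preserves_event_types(self, toy_annotation):
        ann, registry = toy_annotation
        splice_genes = registry.index[registry["etype"] != "APA"]
        sub = Annotation(genes={g: ann.genes[g] for g in splice_genes})
        fwd = {e.gene: e.etype for e in enumerate_events(sub)}
        rev = {e.gene: e.etype for e in enumerate_events(_reflect(sub))}
        assert fwd == rev  # SE/RI/MX invariant, A5<->A3 and AF<->AL both flip

    def test_all_seven_types_realizable(self, toy_annotation):
        ann, registry = toy_annotation
        types = {e.etype for e in enumerate_events(ann)}
        assert types == set(EVENT_TYPES)

    def test_overlapping_exons_rejected(self):
        gene = Gene("g", "chr1", "+")
        with pytest.raises(ValueError, match="overlap"):
            gene.add_transcript("t", [(100, 300), (200, 400)])


class TestPsi:
    def _event(self):
        ann = _gene(
            "+",
            [
                [(100, 200), (300, 400), (500, 600)],
                [(100, 200), (500, 600)],
            ],
        )
        return enumerate_events(ann)

    def test_simple_ratio(self):
        events = self._event()
        tpm = pd.DataFrame({"s1": [3.0, 1.0]}, index=["g.t1", "g.t2"])
        psi = compute_psi(events, tpm)
        assert psi.iloc[0, 0] == pytest.approx(0.75)

    def test_below_floor_is_missing(self):
        events = self._event()
        tpm = pd.DataFrame({"s1": [0.0, 0.0]}, index=["g.t1", "g.t2"])
        assert np.isnan(compute_psi(events, tpm).iloc[0, 0])

    def test_matches_brute_force(self, rng):
        events = self._event()
        tpm = pd.DataFrame(
            rng.uniform(0, 10, size=(2, 8)),
            index=["g.t1", "g.t2"],
            columns=[f"s{i}" for i in range(8)],
        )
        psi = compute_psi(events, tpm)
        expected = tpm.loc["g.t1"] / (tpm.loc["g.t1"] + tpm.loc["g.t2"])
        assert np.allclose(psi.iloc[0], expected)

    def test_complement_symmetry(self, rng):
        events = self._event()
        tpm = pd.DataFrame(
            rng.uniform(1, 10, size=(2, 5)),
            index=["g.t1", "g.t2"],
            columns=[f"s{i}" for i in range(5)],
        )
        psi = compute_psi(events, tpm)
        swapped = events[0]
        swapped.inclusion, swapped.exclusion = swapped.exclusion, swapped.inclusion
        psi_swapped = compute_psi([swapped], tpm)
        assert np.allclose(psi.iloc[0] + psi_swapped.iloc[0], 1.0)

    def test_bounds(self, rng):
        events = self._event()
        tpm = pd.DataFrame(
            rng.uniform(0, 5, size=(2, 20)),
            index=["g.t1", "g.t2"],
            columns=[f"s{i}" for i in range(20)],
        )
        vals = compute_psi(events, tpm).to_numpy()
        vals = vals[np.isfinite(vals)]
        assert np.all((vals >= 0) & (vals <= 1))


def _psi_frame(rng, n_events, groups=(6, 6), noise=0.05, planted=None):
    cols = [f"a{i}" for i in range(groups[0])] + [f"b{i}" for i in range(groups[1])]
    base = rng.uniform(0.2, 0.8, n_events)
    x = np.clip(base[:, None] + rng.normal(0, noise, (n_events, len(cols))), 0, 1)
    psi = pd.DataFrame(x, columns=cols, index=[f"e{i}" for i in range(n_events)])
    if planted:
        for i, (lo, hi, pl_noise) in planted.items():
            row = np.r_[np.full(groups[0], lo), np.full(groups[1], hi)]
            psi.iloc[i] = np.clip(row + rng.normal(0, pl_noise, len(cols)), 0, 1)
    group_of = pd.Series([3] * groups[0] + [20] * groups[1], index=cols)
    expr = pd.Series(rng.uniform(0, 3, n_events), index=psi.index)
    return psi, expr, group_of


class TestDpsi:
    def test_planted_shift_significant(self, rng):
        psi, expr, groups = _psi_frame(
            rng, 600, planted={i: (0.3, 0.7, 0.02) for i in range(10)}
        )
        res = splicing.test_dpsi(psi, expr, groups, (20, 3))
        assert res.iloc[:10]["significant"].all()
        assert np.allclose(res.iloc[:10]["dpsi"], 0.4, atol=0.05)

    def test_constant_psi_null(self):
        cols = [f"s{i}" for i in range(12)]
        psi = pd.DataFrame(0.5, index=["e0"], columns=cols)
        expr = pd.Series([1.0], index=["e0"])
        groups = pd.Series([3] * 6 + [20] * 6, index=cols)
        res = splicing.test_dpsi(psi, expr, groups, (20, 3))
        assert res.loc["e0", "dpsi"] == 0.0
        assert res.loc["e0", "p"] == pytest.approx(1.0)

    def test_null_type_one_at_most_nominal(self, rng):
        psi, expr, groups = _psi_frame(rng, 2000)
        res = splicing.test_dpsi(psi, expr, groups, (20, 3))
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert (res["p"] < 0.05).mean() <= 0.05 + half_width


class TestOverlapAndTrend:
    def test_paper_scale_overlap_magnitude(self):
        _, p, log10p = overlap_test(883, 835, 244, 65311)
        assert log10p <= -250

    def test_forced_total_overlap_p_one(self):
        _, p, _ = overlap_test(10, 10, 10, 10)
        assert p == pytest.approx(1.0)

    def test_small_instance_matches_enumeration(self):
        import itertools

        n_a, n_b, k, universe = 5, 4, 3, 20
        hits = total = 0
        for draw in itertools.combinations(range(universe), n_b):
            total += 1
            if sum(1 for x in draw if x < n_a) >= k:
                hits += 1
        _, p, _ = overlap_test(n_a, n_b, k, universe)
        assert p == pytest.approx(hits / total, rel=1e-9)

    def test_trend_uniform_counts(self):
        stat, p = trend_test([7, 7, 7])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_trend_closed_form(self):
        # (10-20)^2/20 * 2 = 10 on 1 df
        stat, p = trend_test([10, 30])
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(0.001565, abs=1e-5)

    def test_trend_matches_brute_force(self, rng):
        counts = rng.integers(1, 50, size=6)
        stat, _ = trend_test(counts)
        e = counts.mean()
        assert stat == pytest.approx(((counts - e) ** 2 / e).sum())

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            trend_test([0, 0, 0])
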