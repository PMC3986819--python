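import numpy as np
import pytest
from scipy import stats

from neophase import annotate as ann
from neophase import simdata as sd
from neophase.mapper import revcomp
from neophase.seqio import Transcript


def _random_cds(rng, n_codons):
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


class TestAssignIdsRbh:
    def test_mutual_best_assigned(self):
        rng = np.random.default_rng(0)
        seq = _random_cds(rng, 100)
        q = Transcript(id="q1", bases=seq)
        r = Transcript(id="r1", bases=seq)
        (a,) = ann.assign_ids_rbh([q], [r])
        assert (a.transcript_id, a.reference_id) == ("q1", "r1")
        assert not a.tie_broken

    def test_non_reciprocal_unassigned(self):
        # scores: q1 prefers r1, but r1's best is q2
        matrix = {
            ("A1", "B1"): 10,
            ("A1", "B2"): 5,
            ("A2", "B1"): 20,
            ("A2", "B2"): 1,
            ("A3", "B1"): 1,
            ("A3", "B2"): 30,
        }
        qs = [Transcript(id=q, bases="ACGT") for q in ("A1", "A2", "A3")]
        rs = [Transcript(id=r, bases="ACGT") for r in ("B1", "B2")]

        def scorer_factory(mat, by_query=True):
            def scorer(a, b):
                raise AssertionError  # not used; we pass id-based scorer below

            return scorer

        # id-based scorer: look up ids via closure over sequences is not
        # possible, so give each transcript a unique sequence key instead
        seqs = {"A1": "AAAA", "A2": "CCCC", "A3": "GGGG", "B1": "TTTT", "B2": "ACAC"}
        qs = [Transcript(id=q, bases=seqs[q]) for q in ("A1", "A2", "A3")]
        rs = [Transcript(id=r, bases=seqs[r]) for r in ("B1", "B2")]
        inv = {v: k for k, v in seqs.items()}

        def scorer(a, b):
            ia, ib = inv[a], inv[b]
            key = (ia, ib) if ia.startswith("A") else (ib, ia)
            return float(matrix[key])

        got = {
            (a.transcript_id, a.reference_id)
            for a in ann.assign_ids_rbh(qs, rs, scorer)
        }
        # brute-force best-hit matrix: A2<->B1 and A3<->B2 are mutual
        assert got == {("A2", "B1"), ("A3", "B2")}

    def test_tie_broken_lexicographically_and_flagged(self):
        rng = np.random.default_rng(1)
        seq = _random_cds(rng, 80)
        q1 = Transcript(id="q1", bases=seq)
        q2 = Transcript(id="q2", bases=seq)
        r = Transcript(id="r1", bases=seq)
        assignments = ann.assign_ids_rbh([q1, q2], [r])
        assert len(assignments) == 1
        a = assignments[0]
        assert a.transcript_id == "q1" and a.tie_broken

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        seqs = {}
        for i in range(4):
            seqs[f"x{i}"] = _random_cds(rng, 60)
        xs = [Transcript(id=k, bases=v) for k, v in seqs.items()]
        ys = [
            Transcript(id=f"y{i}", bases=seqs[f"x{i}"][: 150 + 3 * i])
            for i in range(4)
        ]
        fwd = {
            (a.transcript_id, a.reference_id) for a in ann.assign_ids_rbh(xs, ys)
        }
        rev = {
            (a.reference_id, a.transcript_id) for a in ann.assign_ids_rbh(ys, xs)
        }
        assert fwd == rev


class TestMergeFragments:
    def test_exact_overlap_merged(self):
        rng = np.random.default_rng(3)
        whole = _random_cds(rng, 120)
        a = Transcript(id="a", bases=whole[:200])
        b = Transcript(id="b", bases=whole[150:330])
        merged = ann.merge_fragments([a, b])
        assert len(merged) == 1
        assert merged[0].bases == whole[:330]
        assert len(merged[0].bases) == 200 + 180 - 50

    def test_short_overlap_unmerged(self):
        rng = np.random.default_rng(4)
        whole = _random_cds(rng, 120)
        a = Transcript(id="a", bases=whole[:200])
        b = Transcript(id="b", bases=whole[170:330])  # 30 bp < 40
        assert len(ann.merge_fragments([a, b])) == 2

    def test_low_identity_overlap_unmerged(self):
        rng = np.random.default_rng(5)
        whole = _random_cds(rng, 120)
        a = Transcript(id="a", bases=whole[:200])
        tail = list(whole[150:330])
        for p in (5, 15, 25):  # 3 mismatches in the 50bp overlap: 94% < 99%
            tail[p] = "A" if tail[p] != "A" else "C"
        b = Transcript(id="b", bases="".join(tail))
        assert len(ann.merge_fragments([a, b])) == 2


class TestScaffoldByProtein:
    def test_gap_filled_with_three_n_per_residue(self):
        rng = np.random.default_rng(6)
        cds = _random_cds(rng, 250)
        protein = ann.translate(cds)
        frag1 = Transcript(id="f1", bases=cds[0:300])  # residues 0..100
        frag2 = Transcript(id="f2", bases=cds[450:750])  # residues 150..250
        (scaffold,) = ann.scaffold_by_protein([frag1, frag2], "p", protein)
        assert scaffold.bases == cds[0:300] + "N" * 150 + cds[450:750]

    def test_single_fragment_unchanged(self):
        t = Transcript(id="f1", bases="ATGGCTGCT")
        assert ann.scaffold_by_protein([t], "p", "MAA") == [t]

    def test_reverse_fragment_reoriented(self):
        rng = np.random.default_rng(7)
        cds = _random_cds(rng, 250)
        protein = ann.translate(cds)
        frag1 = Transcript(id="f1", bases=cds[0:300])
        frag2 = Transcript(id="f2", bases=revcomp(cds[450:750]))
        (scaffold,) = ann.scaffold_by_protein([frag1, frag2], "p", protein)
        assert scaffold.bases == cds[0:300] + "N" * 150 + cds[450:750]

    def test_conflicting_placements_unscaffolded(self, caplog):
        rng = np.random.default_rng(8)
        cds = _random_cds(rng, 300)
        protein = ann.translate(cds)
        # two fragments covering overlapping protein spans that cannot be
        # nucleotide-merged (diverged overlap)
        frag1 = Transcript(id="f1", bases=cds[0:450])
        middle = list(cds[300:750])
        for p in range(0, 150, 7):
            middle[p] = "A" if middle[p] != "A" else "C"
        frag2 = Transcript(id="f2", bases="".join(middle))
        out = ann.scaffold_by_protein([frag1, frag2], "p", protein)
        assert len(out) == 2


class TestAlignToReferenceCds:
    def test_identical(self):
        rng = np.random.default_rng(9)
        cds = Transcript(id="c", bases=_random_cds(rng, 200))
        t = Transcript(id="t", bases=cds.bases)
        aln = ann.align_to_reference_cds(t, cds)
        assert aln.identity == pytest.approx(1.0)
        assert "-" not in aln.aligned_tx and "-" not in aln.aligned_ref
        assert not aln.unalignable

    def test_two_bp_deletion_found(self):
        rng = np.random.default_rng(10)
        cds = Transcript(id="c", bases=_random_cds(rng, 200))
        t = Transcript(id="t", bases=cds.bases[:100] + cds.bases[102:])
        aln = ann.align_to_reference_cds(t, cds)
        assert not aln.unalignable
        n_gap_cols = aln.aligned_tx.count("-")
        assert n_gap_cols == 2

    def test_unrelated_unalignable(self):
        rng = np.random.default_rng(11)
        cds = Transcript(id="c", bases=_random_cds(rng, 150))
        t = Transcript(id="t", bases=_random_cds(rng, 150))
        aln = ann.align_to_reference_cds(t, cds)
        assert aln.unalignable


class TestClassifyOrf:
    def _classify(self, tx_bases, cds_bases):
        cds = Transcript(id="c", bases=cds_bases)
        t = Transcript(id="t", bases=tx_bases)
        return ann.classify_orf(ann.align_to_reference_cds(t, cds), cds)

    def test_identical_intact(self):
        rng = np.random.default_rng(12)
        cds = _random_cds(rng, 200)
        o = self._classify(cds, cds)
        assert o.status == ann.STATUS_INTACT
        assert o.first_ptc_codon_index is None
        assert not o.frameshift_positions

    def test_ptc_at_quarter(self):
        rng = np.random.default_rng(13)
        cds = _random_cds(rng, 200)
        mutated = cds[: 50 * 3] + "TAA" + cds[50 * 3 + 3 :]
        o = self._classify(mutated, cds)
        assert o.status == ann.STATUS_PTC
        assert o.first_ptc_codon_index == 50
        assert o.first_ptc_relative == pytest.approx(0.25)

    def test_frameshift_only_when_shifted_frame_stop_free(self):
        # stop-free shifted frame: GGC repeats contain no stops in any frame
        cds = "ATG" + "GGC" * 60 + "TAA"
        mutated = cds[: 30 * 3] + cds[30 * 3 + 1 :]  # 1bp deletion at codon 30
        o = self._classify(mutated, cds)
        assert o.status == ann.STATUS_FRAMESHIFT
        assert len(o.frameshift_positions) == 1
        assert o.frameshift_ref_codon_indices[0] == pytest.approx(30, abs=1)

    def test_frameshift_with_downstream_stop(self):
        rng = np.random.default_rng(14)
        cds = _random_cds(rng, 300)
        mutated = cds[: 30 * 3] + cds[30 * 3 + 1 :]
        o = self._classify(mutated, cds)
        # random sequence: the shifted frame almost surely hits a stop
        assert o.status in (ann.STATUS_BOTH, ann.STATUS_FRAMESHIFT)

    def test_bad_reference_rejected(self):
        cds = Transcript(id="c", bases="ATGAAA")  # no stop codon
        t = Transcript(id="t", bases="ATGAAA")
        with pytest.raises(ValueError):
            ann.classify_orf(ann.align_to_reference_cds(t, cds), cds)


class TestUtr3Lengths:
    def _orf(self, first_stop_end, ptc_codon=None, anc_stop_end=None):
        return ann.OrfAnnotation(
            transcript_id="t",
            status=ann.STATUS_PTC if ptc_codon is not None else ann.STATUS_INTACT,
            first_ptc_codon_index=ptc_codon,
            first_stop_end_tpos=first_stop_end,
            ancestral_stop_end_tpos=anc_stop_end,
        )

    def test_simple_distance(self):
        t = Transcript(id="t", bases="A" * 1000)
        assert ann.utr3_lengths(t, self._orf(700)) == (300, None)

    def test_ptc_reports_both(self):
        t = Transcript(id="t", bases="A" * 1000)
        assert ann.utr3_lengths(t, self._orf(300, ptc_codon=10, anc_stop_end=900)) == (
            700,
            100,
        )

    def test_stop_at_end_zero(self):
        t = Transcript(id="t", bases="A" * 300)
        assert ann.utr3_lengths(t, self._orf(300)) == (0, None)

    def test_no_stop_undefined(self):
        t = Transcript(id="t", bases="A" * 300)
        assert ann.utr3_lengths(t, self._orf(None)) == (None, None)


@pytest.fixture(scope="module")
def ptc_dataset():
    cfg = sd.SimConfig(
        n_genes=150,
        mean_cds_codons=150,
        frac_ptc=1.0,
        frac_frameshift=0.0,
        frac_neoY_silenced=0.0,
        frac_neoY_deleted=0.0,
        frac_neoX_deleted=0.0,
        seed=5,
    )
    return sd.simulate_gene_set(cfg)


class TestLesionRecoveryOnSimulatedTruth:
    """classify_orf against the simulator's true haplotype sequences."""

    def test_ptc_codon_recovered_exactly(self, ptc_dataset):
        truth = ptc_dataset.truth
        cds_by_gene = {c.id: c for c in ptc_dataset.reference_cds}
        rels = []
        for g in truth.genes:
            cds = cds_by_gene[f"ref_{g.gene_id}"]
            tx = Transcript(id=g.gene_id, bases=g.neoY_tx)
            o = ann.classify_orf(ann.align_to_reference_cds(tx, cds), cds)
            assert o.first_ptc_codon_index == g.ptc_codon_index, g.gene_id
            rels.append(o.first_ptc_relative)
        assert all(0 <= r <= 1 for r in rels)

    def test_ptc_positions_uniform(self, ptc_dataset):
        truth = ptc_dataset.truth
        rels = [g.ptc_codon_index / g.n_codons for g in truth.genes]
        assert stats.kstest(rels, "uniform").pvalue > 0.01

    def test_frameshift_recovery_and_no_false_intact(self):
        cfg = sd.SimConfig(
            n_genes=60,
            mean_cds_codons=150,
            frac_ptc=0.0,
            frac_frameshift=1.0,
            frac_neoY_silenced=0.0,
            frac_neoY_deleted=0.0,
            frac_neoX_deleted=0.0,
            seed=6,
        )
        bundle = sd.simulate_gene_set(cfg)
        cds_by_gene = {c.id: c for c in bundle.reference_cds}
        for g in bundle.truth.genes:
            cds = cds_by_gene[f"ref_{g.gene_id}"]
            tx = Transcript(id=g.gene_id, bases=g.neoY_tx)
            o = ann.classify_orf(ann.align_to_reference_cds(tx, cds), cds)
            assert o.status in (ann.STATUS_FRAMESHIFT, ann.STATUS_BOTH), g.gene_id
            assert any(
                abs(c - g.frameshift_codon_index) <= 1
                for c in o.frameshift_ref_codon_indices
            ), g.gene_id

    def test_intact_genes_never_called_disrupted(self):
        cfg = sd.SimConfig(
            n_genes=60,
            mean_cds_codons=150,
            frac_ptc=0.0,
            frac_frameshift=0.0,
            frac_neoY_silenced=0.0,
            frac_neoY_deleted=0.0,
            frac_neoX_deleted=0.0,
            seed=8,
        )
        bundle = sd.simulate_gene_set(cfg)
        cds_by_gene = {c.id: c for c in bundle.reference_cds}
        for g in bundle.truth.genes:
            cds = cds_by_gene[f"ref_{g.gene_id}"]
            tx = Transcript(id=g.gene_id, bases=g.neoY_tx)
            o = ann.classify_orf(ann.align_to_reference_cds(tx, cds), cds)
            assert o.status == ann.STATUS_INTACT, g.gene_id
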