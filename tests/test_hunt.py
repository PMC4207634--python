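"""Profile construction, six-frame scanning, dedupe, classification, NJ."""

import itertools

import numpy as np
import pytest

from lephox import hunt, synthetic
from lephox._seq import revcomp
from lephox.hunt import (
    DistanceMatrix,
    ProfileHit,
    build_profile,
    classify_hit,
    dedupe_hits,
    nj_tree,
    p_distance,
    scan_contigs,
)


@pytest.fixture(scope="module")
def zen_profile(reference_panel):
    members = [s for _, cls, s in reference_panel if cls == "zen/Shx"]
    return build_profile(members)


class TestBuildProfile:
    def test_large_pseudocount_flattens_scores(self, reference_panel):
        seq = reference_panel[0][2]
        profile = build_profile([seq], pseudocount=1e9)
        assert np.abs(profile.log_odds).max() < 1e-6

    def test_conserved_column_sign(self):
        bg = np.full(20, (1 - 0.01) / 19)
        bg[synthetic.AMINO_ACIDS.index("W") if hasattr(synthetic, "AMINO_ACIDS") else 17] = 0.01
        from lephox._seq import AA_INDEX

        bg = np.full(20, (1 - 0.01) / 19)
        bg[AA_INDEX["W"]] = 0.01
        profile = build_profile(["W" * 60], pseudocount=0.1, background=bg)
        assert profile.log_odds[0, AA_INDEX["W"]] > 0
        assert profile.log_odds[0, AA_INDEX["A"]] < 0

    def test_member_beats_shuffled_permutations(self, zen_profile, reference_panel):
        seq = next(s for _, cls, s in reference_panel if cls == "zen/Shx")
        member_score = zen_profile.score_peptide(seq)
        rng = np.random.default_rng(1)
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(seq)))
            assert zen_profile.score_peptide(shuffled) <= member_score

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["AAA", "AA"])


class TestScanContigs:
    def plant(self, protein, strand, pos=300, length=3000, seed=8):
        spec = synthetic.SyntheticGenomeSpec(
            length=length, seed=seed, planted_genes=[("g", protein, pos, strand)]
        )
        contigs, _ = synthetic.gen_genome(spec)
        return contigs

    def test_forward_plant_found_at_exact_coordinates(self, zen_profile, reference_panel):
        seq = next(s for _, cls, s in reference_panel if cls == "zen/Shx")
        contigs = self.plant(seq, "+")
        hits = scan_contigs(contigs, zen_profile, 1e-3)
        assert hits and (hits[0].start, hits[0].end, hits[0].strand) == (300, 480, "+")
        assert hits[0].peptide == seq

    def test_reverse_plant_reported_in_forward_coordinates(
        self, zen_profile, reference_panel
    ):
        seq = next(s for _, cls, s in reference_panel if cls == "zen/Shx")
        contigs = self.plant(seq, "-")
        hits = scan_contigs(contigs, zen_profile, 1e-3)
        assert hits and (hits[0].start, hits[0].end, hits[0].strand) == (300, 480, "-")
        assert hits[0].peptide == seq

    def test_strand_symmetry(self, zen_profile, reference_panel):
        """Scanning the reverse complement mirrors hit coordinates."""
        seq = next(s for _, cls, s in reference_panel if cls == "zen/Shx")
        contigs = self.plant(seq, "+")
        (name, fwd), = contigs.items()
        hits_f = scan_contigs({name: fwd}, zen_profile, 1e-3)
        hits_r = scan_contigs({name: revcomp(fwd)}, zen_profile, 1e-3)
        L = len(fwd)
        mirrored = {(L - h.end, L - h.start, "-" if h.strand == "+" else "+")
                    for h in hits_r}
        assert {(h.start, h.end, h.strand) for h in hits_f} == mirrored

    def test_short_contig_skipped(self, zen_profile):
        assert scan_contigs({"tiny": "ACGT" * 10}, zen_profile, 1.0) == []

    def test_hit_span_is_180nt(self, zen_profile, reference_panel):
        seq = next(s for _, cls, s in reference_panel if cls == "zen/Shx")
        for strand in "+-":
            hits = scan_contigs(self.plant(seq, strand), zen_profile, 1e-3)
            assert all(h.end - h.start == 180 for h in hits)


def _mk_hit(start, end, score, contig="c"):
    return ProfileHit(contig_id=contig, start=start, end=end, strand="+",
                      frame=0, score=score, evalue_like=0.0, peptide="")


class TestDedupe:
    def test_identical_intervals_keep_best(self):
        hits = [_mk_hit(0, 180, 10.0), _mk_hit(0, 180, 9.0)]
        kept = dedupe_hits(hits)
        assert len(kept) == 1 and kept[0].score == 10.0

    def test_disjoint_hits_kept(self):
        hits = [_mk_hit(0, 180, 5.0), _mk_hit(300, 480, 4.0)]
        assert len(dedupe_hits(hits)) == 2

    def test_different_contigs_never_collapse(self):
        hits = [_mk_hit(0, 180, 5.0, "a"), _mk_hit(0, 180, 4.0, "b")]
        assert len(dedupe_hits(hits)) == 2

    def test_mutually_overlapping_cluster_matches_exhaustive(self):
        """On cliques of mutually overlapping hits, greedy best-first
        equals exhaustive max-weight selection (the single best hit)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 7)
            # staggered chain with >=50% mutual overlap: starts within 90 nt
            starts = np.sort(rng.integers(0, 90, size=n))
            scores = rng.random(n) * 10
            hits = [_mk_hit(int(s), int(s) + 180, float(sc))
                    for s, sc in zip(starts, scores)]
            kept = dedupe_hits(hits)
            # exhaustive: best conflict-free subset by total score
            best_subset, best_total = None, -1.0
            for r in range(1, n + 1):
                for sub in itertools.combinations(hits, r):
                    ok = all(
                        min(a.end, b.end) - max(a.start, b.start) < 90
                        for a, b in itertools.combinations(sub, 2)
                    )
                    total = sum(h.score for h in sub)
                    if ok and total > best_total:
                        best_subset, best_total = sub, total
            assert {h.score for h in kept} == {h.score for h in best_subset}


class TestClassify:
    def test_exact_zen_reference_classified(self, reference_panel):
        rid, cls, seq = next(r for r in reference_panel if r[1] == "zen/Shx")
        hit = _mk_hit(0, 180, 100.0)
        hit.peptide = seq
        c = classify_hit(hit, reference_panel)
        assert c.assigned_class == "zen/Shx"
        assert c.nearest_reference[1] == 0.0
        assert c.diagnostic_flags["S10"] is True

    def test_non_hox3_classes_lack_s10(self, reference_panel):
        for rid, cls, seq in reference_panel:
            hit = _mk_hit(0, 180, 1.0)
            hit.peptide = seq
            c = classify_hit(hit, reference_panel)
            assert c.diagnostic_flags["S10"] == (cls == "zen/Shx")

    def test_distant_peptide_unknown(self, reference_panel):
        hit = _mk_hit(0, 180, 1.0)
        hit.peptide = "G" * 60  # far from every reference
        assert classify_hit(hit, reference_panel).assigned_class == "unknown"

    def test_ambiguous_peptide_unknown(self, reference_panel):
        hit = _mk_hit(0, 180, 1.0)
        hit.peptide = "X" * 10 + reference_panel[0][2][10:]
        assert classify_hit(hit, reference_panel).assigned_class == "unknown"

    def test_mutated_references_recovered(self, reference_panel):
        """Peptides mutated at 10% of sites keep their class >=95% of runs."""
        rng = np.random.default_rng(42)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        correct = total = 0
        for _ in range(100):
            rid, cls, seq = reference_panel[rng.integers(len(reference_panel))]
            pep = list(seq)
            for p in rng.choice(60, size=6, replace=False):
                pep[p] = aas[rng.integers(20)]
            hit = _mk_hit(0, 180, 1.0)
            hit.peptide = "".join(pep)
            total += 1
            correct += classify_hit(hit, reference_panel).assigned_class == cls
        assert correct / total >= 0.95


class TestPlantedGenomeRecovery:
    def test_all_ten_classes_recovered(self, planted_hox_genome, reference_panel):
        contigs, truth = planted_hox_genome
        results = hunt.hunt_genome(contigs, reference_panel, 1e-6)
        coords = {(r.start, r.end, r.strand): r.name for r in truth.itertuples()}
        assert len(results) == 10
        for c in results:
            h = c.hit
            name = coords[(h.start, h.end, h.strand)]
            want = name.rsplit("_", 1)[0].replace("zen_Shx", "zen/Shx")
            assert c.assigned_class == want


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            taxa=["a", "b", "c"],
            values=np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float),
        )
        nwk = nj_tree(dm)
        # three-point solution: a=2, b=3, c=7
        assert nwk == "(a:2.000000,b:3.000000,c:7.000000);"

    def test_four_taxon_additive_topology(self):
        """NJ recovers the split of an additive matrix, matching the
        least-squares-best topology found by exhaustive search."""
        import io

        from Bio import Phylo

        # tree ((a,b),(c,d)) with internal branch 4
        dm = DistanceMatrix(
            taxa=["a", "b", "c", "d"],
            values=np.array(
                [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 5], [10, 11, 5, 0]],
                float,
            ),
        )
        tree = Phylo.read(io.StringIO(nj_tree(dm)), "newick")
        names = lambda cl: {t.name for t in cl.get_terminals()}
        splits = {frozenset(names(cl)) for cl in tree.get_nonterminals()}
        internal = [s for cl in tree.get_nonterminals() for s in [names(cl)]
                    if len(s) == 2]
        assert {"a", "b"} in internal or {"c", "d"} in internal

    def test_five_taxon_ultrametric_recovery(self):
        import io

        from Bio import Phylo

        # ultrametric: ((a,b),(c,(d,e))) with heights 1,2,3 / 1.5
        taxa = list("abcde")
        D = np.zeros((5, 5))
        def h(x, y):
            pairs = {frozenset("ab"): 1, frozenset("de"): 1.5,
                     frozenset("cd"): 2, frozenset("ce"): 2}
            return pairs.get(frozenset(x + y), 3)
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i != j:
                    D[i, j] = 2 * h(x, y)
        tree = Phylo.read(io.StringIO(nj_tree(DistanceMatrix(taxa, D))), "newick")
        full = frozenset(taxa)
        splits = set()
        for cl in tree.get_nonterminals():
            s = frozenset(t.name for t in cl.get_terminals())
            if 1 < len(s) < 5:
                splits.add(min(s, full - s, key=sorted))
        assert min(frozenset("ab"), full - frozenset("ab"), key=sorted) in splits
        assert min(frozenset("de"), full - frozenset("de"), key=sorted) in splits

    def test_matches_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(6)]
        # random additive-ish matrix: distances from random tree via
        # random positive branch sums
        base = rng.random((6, 6)) * 5 + 1
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        ours = nj_tree(DistanceMatrix(taxa, D))
        theirs = sk_nj(SkDM(D, ids=taxa))
        import io

        from Bio import Phylo

        t1 = Phylo.read(io.StringIO(ours), "newick")
        def splits(tree, names):
            out = set()
            for cl in tree.get_nonterminals():
                s = frozenset(x.name for x in cl.get_terminals())
                if 1 < len(s) < len(names) - 1:
                    out.add(min(s, frozenset(names) - s, key=sorted))
            return out
        s1 = splits(t1, taxa)
        s2 = set()
        for node in theirs.non_tips():
            s = frozenset(x.name for x in node.tips())
            if 1 < len(s) < 5:
                s2.add(min(s, frozenset(taxa) - s, key=sorted))
        assert s1 == s2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], values=np.array([[0, 1], [2, 0]], float))
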