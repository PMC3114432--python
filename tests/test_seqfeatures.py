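"""Codon/protein feature panel: counts, RSCU, CAI, Nc, composition,
ProtParam-style indices and correspondence analysis."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protimpute.seqfeatures import (
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    CodonProfile,
    ReferenceCodonWeights,
    assemble_features,
    build_reference_weights,
    cai,
    codon_counts,
    correspondence_analysis,
    correspondence_axes,
    effective_number_of_codons,
    gc_content,
    protein_indices,
    rscu,
    third_position_composition,
    translate_cds,
)

#: GRAVY, AROMO, instability and average MW recorded from the reference
#: ProtParam implementation (Bio.SeqUtils.ProtParam.ProteinAnalysis)
PROTPARAM_FIXTURES = [
    ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", -0.403030, 0.090909, 53.548485, 3935.5547),
    ("ACDEFGHIKLMNPQRSTVWY", -0.490000, 0.150000, 84.740000, 2395.7134),
    ("GAVLIPFMWSTCYNQDEKRH", -0.490000, 0.150000, 45.235000, 2395.7134),
    ("MSTNPKPQRKTKRNTNRRPQDVKFPGG", -2.066667, 0.037037, 84.796296, 3139.5541),
    ("WWFYHHKRDE", -2.210000, 0.400000, 110.221000, 1503.6201),
    ("LLLLVVVVAAAAIIII", 3.575000, 0.000000, 9.375000, 1604.1117),
]

#: RSCU of a 20-codon toy CDS recorded from seqinr::uco(index="rscu")
SEQINR_TOY_CDS = "ATGGGAGGCGGAGGTCTGCTACTGAAGAAAAAATTCTTTGAAGATGGAGGAGGAATGTAA"
SEQINR_RSCU = {
    "AAA": 1.3333333333, "AAG": 0.6666666667, "ATG": 1.0,
    "CTA": 2.0, "CTG": 4.0, "GAA": 2.0, "GAT": 2.0,
    "GGA": 2.8571428571, "GGC": 0.5714285714, "GGT": 0.5714285714,
    "TTC": 1.0, "TTT": 1.0,
}


def profile_from_counts(counts: dict) -> CodonProfile:
    return CodonProfile("toy", dict(counts), sum(counts.values()))


class TestCodonCounts:
    def test_direct_count_with_terminal_stop(self):
        p = codon_counts("ATGTAA")
        assert p.counts == {"ATG": 1, "TAA": 1}
        assert p.has_terminal_stop

    def test_repeated_codon(self):
        assert codon_counts("ATGATG").counts == {"ATG": 2}

    def test_frame_error(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_counts("ATGA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            codon_counts("ATGTAAATG")

    def test_ambiguous_codon_dropped_below_threshold(self):
        seq = "ATG" + "GCA" * 120 + "GCN"
        with pytest.warns(UserWarning, match="ambiguous"):
            p = codon_counts(seq)
        assert p.length_codons == 121

    def test_too_many_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            codon_counts("ATGNNNNNN")


class TestRscu:
    def test_uniform_family(self):
        p = profile_from_counts({"GGA": 2, "GGC": 2, "GGG": 2, "GGT": 2})
        r = rscu(p)
        assert all(r[c] == pytest.approx(1.0) for c in ("GGA", "GGC", "GGG", "GGT"))

    def test_fully_skewed_family(self):
        p = profile_from_counts({"GGA": 4})
        r = rscu(p)
        assert r["GGA"] == pytest.approx(4.0)
        assert r["GGC"] == 0 and r["GGG"] == 0 and r["GGT"] == 0

    def test_unobserved_family_is_nan(self):
        p = profile_from_counts({"GGA": 1})
        assert math.isnan(rscu(p)["TTT"])

    def test_matches_recorded_seqinr_values(self):
        p = codon_counts(SEQINR_TOY_CDS)
        r = rscu(p)
        for codon, expected in SEQINR_RSCU.items():
            assert r[codon] == pytest.approx(expected, abs=1e-9), codon


class TestReferenceWeightsAndCai:
    def test_uniform_reference_gives_unit_weights(self):
        counts = {c: 3 for c in SENSE_CODONS}
        w = build_reference_weights([profile_from_counts(counts)])
        assert all(v == 1.0 for v in w.w.values())

    def test_two_fold_family_ratio(self):
        w = build_reference_weights([profile_from_counts({"GAA": 2, "GAG": 1})])
        assert w.w["GAA"] == 1.0
        assert w.w["GAG"] == pytest.approx(0.5)

    def test_pooling_across_genes(self):
        profiles = [
            profile_from_counts({"GAA": 1, "GAG": 1}),
            profile_from_counts({"GAA": 3}),
        ]
        w = build_reference_weights(profiles)
        # pooled (4, 1): w = 1, 0.25
        assert w.w["GAA"] == 1.0 and w.w["GAG"] == pytest.approx(0.25)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_reference_weights([])

    def test_cai_of_all_optimal_gene(self):
        ref = build_reference_weights([profile_from_counts({"GAA": 4, "GAG": 1})])
        assert cai(profile_from_counts({"GAA": 10}), ref) == pytest.approx(1.0)

    def test_cai_constant_weights(self):
        w = ReferenceCodonWeights(
            w={c: 0.5 for aa in SYNONYMOUS_FAMILIES for c in SYNONYMOUS_FAMILIES[aa]},
            reference_gene_ids=[],
        )
        p = profile_from_counts({"GAA": 3, "GGC": 2})
        assert cai(p, w) == pytest.approx(0.5)

    def test_cai_log_domain_oracle(self, rng):
        """Count-weighted geometric mean agrees with a brute-force product."""
        ref = build_reference_weights(
            [profile_from_counts({c: int(k) for c, k in
                                  zip(SENSE_CODONS, rng.integers(0, 20, 61))})]
        )
        counts = {c: int(k) for c, k in zip(SENSE_CODONS, rng.integers(0, 9, 61)) if k}
        p = profile_from_counts(counts)
        value = cai(p, ref)
        eligible = {
            c for aa, fam in SYNONYMOUS_FAMILIES.items() if len(fam) > 1 for c in fam
        }
        prod, n = 1.0, 0
        for c, k in counts.items():
            if c in eligible:
                prod *= ref.w[c] ** k
                n += k
        assert value == pytest.approx(prod ** (1.0 / n), rel=1e-9)

    def test_cai_invariant_to_duplication(self):
        ref = build_reference_weights(
            [profile_from_counts({"GAA": 4, "GAG": 1, "GGA": 3, "GGC": 1})]
        )
        p1 = profile_from_counts({"GAA": 2, "GGC": 1})
        p2 = profile_from_counts({"GAA": 4, "GGC": 2})
        assert cai(p1, ref) == pytest.approx(cai(p2, ref), rel=1e-12)

    def test_cai_without_eligible_codons(self):
        ref = build_reference_weights([profile_from_counts({"GAA": 1})])
        with pytest.raises(ValueError, match="eligible"):
            cai(profile_from_counts({"ATG": 5, "TGG": 2}), ref)


class TestEffectiveNumberOfCodons:
    def test_single_codon_per_amino_acid_is_20(self):
        counts = {SYNONYMOUS_FAMILIES[aa][0]: 10 for aa in SYNONYMOUS_FAMILIES}
        assert effective_number_of_codons(profile_from_counts(counts)) == 20.0

    def test_uniform_usage_clamps_to_61(self):
        counts = {c: 50 for c in SENSE_CODONS}
        assert effective_number_of_codons(profile_from_counts(counts)) == 61.0

    def test_hand_computed_wright_fixture(self):
        """Constructed profile with F2=1/2, F3=1/3, F4=1/2, F6=1/5 -> Nc=48."""
        counts = {}
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            if len(fam) == 2:
                counts[fam[0]], counts[fam[1]] = 3, 1
            elif len(fam) == 3:
                counts[fam[0]], counts[fam[1]] = 2, 2
            elif len(fam) == 4:
                counts[fam[0]], counts[fam[1]] = 3, 1
            elif len(fam) == 6:
                counts[fam[0]], counts[fam[1]] = 3, 1
                counts[fam[2]], counts[fam[3]] = 1, 1
        nc = effective_number_of_codons(profile_from_counts(counts))
        assert nc == pytest.approx(2 + 9 / 0.5 + 1 / (1 / 3) + 5 / 0.5 + 3 / 0.2)
        assert nc == pytest.approx(48.0)

    def test_skew_decreases_nc(self):
        even = {c: 10 for c in SENSE_CODONS}
        skewed = dict(even)
        for fam in SYNONYMOUS_FAMILIES.values():
            if len(fam) >= 2:
                skewed[fam[0]] = 18
                for c in fam[1:]:
                    skewed[c] = 2
        assert effective_number_of_codons(
            profile_from_counts(skewed)
        ) < effective_number_of_codons(profile_from_counts(even))

    def test_missing_ile_imputed_from_neighbours(self):
        counts = {}
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            if len(fam) == 3:
                continue  # Ile absent
            counts[fam[0]], counts[fam[1 % len(fam)]] = 3, 1
        nc = effective_number_of_codons(profile_from_counts(counts))
        assert 20 <= nc <= 61 and not math.isnan(nc)

    def test_unobservable_two_fold_class_gives_nan(self):
        counts = {"GGA": 5, "GGC": 5}  # only a 4-fold family observed
        assert math.isnan(effective_number_of_codons(profile_from_counts(counts)))


class TestThirdPosition:
    def test_single_base(self):
        comp = third_position_composition(profile_from_counts({"GGA": 2}))
        assert comp["A3s"] == 1.0 and comp["T3s"] == comp["C3s"] == comp["G3s"] == 0

    def test_uniform_family_quarters(self):
        comp = third_position_composition(
            profile_from_counts({"GGA": 1, "GGC": 1, "GGG": 1, "GGT": 1})
        )
        for key in ("A3s", "T3s", "C3s", "G3s"):
            assert comp[key] == pytest.approx(0.25)
        assert comp["GC3s"] == pytest.approx(0.5)

    def test_met_trp_excluded(self):
        comp = third_position_composition(
            profile_from_counts({"ATG": 50, "TGG": 50, "GGA": 1})
        )
        assert comp["A3s"] == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_composition_sums_to_one(self, seed):
        r = np.random.default_rng(seed)
        counts = {c: int(k) for c, k in zip(SENSE_CODONS, r.integers(0, 10, 61))}
        if sum(counts.values()) == 0:
            counts["GGA"] = 1
        comp = third_position_composition(profile_from_counts(counts))
        assert comp["A3s"] + comp["T3s"] + comp["C3s"] + comp["G3s"] == pytest.approx(
            1.0, abs=1e-9
        )


class TestProteinIndices:
    def test_all_aromatic(self):
        assert protein_indices("FYWFYW")["AROMO"] == pytest.approx(1.0)

    def test_poly_alanine_aliphatic_index(self):
        assert protein_indices("A" * 20)["AliphaticIndex"] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "peptide,gravy,aromo,instability,mw", PROTPARAM_FIXTURES
    )
    def test_matches_protparam_reference(self, peptide, gravy, aromo, instability, mw):
        idx = protein_indices(peptide)
        assert idx["GRAVY"] == pytest.approx(gravy, abs=0.01)
        assert idx["AROMO"] == pytest.approx(aromo, abs=0.01)
        assert idx["InstabilityIndex"] == pytest.approx(instability, abs=0.01)
        assert idx["MolecularWeight"] == pytest.approx(mw, abs=0.01)

    def test_concatenation_preserves_composition_indices(self):
        pep = "MKTAYIAKQRQISFVK"
        one = protein_indices(pep)
        two = protein_indices(pep + pep)
        for key in ("GRAVY", "AROMO", "AliphaticIndex"):
            # composition is unchanged up to the single junction dipeptide
            assert two[key] == pytest.approx(one[key], abs=1e-9)

    def test_length_and_alphabet_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            protein_indices("A")
        with pytest.raises(ValueError, match="non-standard"):
            protein_indices("AXB")


class TestCorrespondenceAnalysis:
    def _chi2_inertia(self, X):
        X = np.asarray(X, dtype=float)
        n = X.sum()
        r = X.sum(1, keepdims=True) / n
        c = X.sum(0, keepdims=True) / n
        E = r * c * n
        return float(np.sum((X - E) ** 2 / E)) / n

    def test_matches_dense_eigen_oracle(self, rng):
        """Row scores agree with an explicit eigen-decomposition of the
        standardized residual cross-product, up to global sign."""
        X = rng.integers(1, 30, size=(4, 3)).astype(float)
        table = pd.DataFrame(X)
        rows, cols, inertia = correspondence_analysis(table)
        P = X / X.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        evals, evecs = np.linalg.eigh(S @ S.T)
        order = np.argsort(evals)[::-1]
        lead = np.sqrt(evals[order[0]]) * evecs[:, order[0]] / np.sqrt(r)
        got = rows.iloc[:, 0].to_numpy()
        assert np.allclose(got, lead, atol=1e-9) or np.allclose(got, -lead, atol=1e-9)

    def test_total_inertia_equals_chi2_over_n(self, rng):
        X = rng.integers(1, 25, size=(6, 5)).astype(float)
        _, _, inertia = correspondence_analysis(pd.DataFrame(X))
        assert inertia.sum() == pytest.approx(self._chi2_inertia(X), rel=1e-9)

    def test_agrees_with_skbio_up_to_sign(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        X = rng.integers(1, 30, size=(6, 4)).astype(float)
        table = pd.DataFrame(
            X, index=[f"g{i}" for i in range(6)], columns=list("abcd")
        )
        rows, _, _ = correspondence_analysis(table)
        res = skbio_ord.ca(table, scaling=1)
        ref = res.samples.to_numpy()
        for a in range(min(3, ref.shape[1])):
            got = rows.iloc[:, a].to_numpy()
            assert np.allclose(got, ref[:, a], atol=1e-8) or np.allclose(
                got, -ref[:, a], atol=1e-8
            ), f"axis {a}"

    def test_row_permutation_equivariance(self, rng):
        X = rng.integers(1, 30, size=(5, 4)).astype(float)
        table = pd.DataFrame(X, index=[f"g{i}" for i in range(5)])
        perm = [3, 1, 4, 0, 2]
        rows1 = correspondence_axes(table, 2)
        rows2 = correspondence_axes(table.iloc[perm], 2)
        np.testing.assert_allclose(
            rows1.iloc[perm].to_numpy(), rows2.to_numpy(), atol=1e-12
        )

    def test_axis_orthogonality_under_ca_inner_product(self, rng):
        X = rng.integers(1, 30, size=(6, 5)).astype(float)
        rows, _, inertia = correspondence_analysis(pd.DataFrame(X))
        r = X.sum(1) / X.sum()
        F = rows.to_numpy()
        G = F.T * r @ F
        np.testing.assert_allclose(G, np.diag(np.diag(G)), atol=1e-9)

    def test_degenerate_table_rejected(self):
        X = pd.DataFrame(np.outer([1, 2, 3], [1, 1, 2]).astype(float))
        with pytest.raises(ValueError, match="axes"):
            correspondence_axes(X, 2)


class TestAssembleFeatures:
    def test_assembles_complete_rows(self, small_dataset):
        feats = small_dataset.features
        assert len(feats) == 200
        core = ["gene_length_log2", "CAI", "Nc", "GC", "GRAVY", "InstabilityIndex",
                "AliphaticIndex", "MolecularWeight", "AA_axis1", "CR_axis1"]
        assert not feats[core].drop(columns=["Nc"]).isna().any().any()
        assert feats["CAI"].between(0, 1).all()
        assert feats["Nc"].dropna().between(20, 61).all()

    def test_gene_without_cds_excluded_with_warning(self, small_dataset):
        anns = list(small_dataset.genome.annotations)
        cds = dict(small_dataset.genome.cds)
        del cds[anns[0].gene_id]
        with pytest.warns(UserWarning, match="lack a CDS"):
            feats = assemble_features(
                anns, cds, reference_gene_ids=small_dataset.genome.reference_gene_ids
            )
        assert anns[0].gene_id not in feats.index

    def test_empty_intersection_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="shared"):
            assemble_features(
                small_dataset.genome.annotations, {"nope": "ATGTAA"},
                reference_gene_ids=["nope"],
            )
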