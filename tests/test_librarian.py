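import math

import numpy as np
import pytest

from nanolibkit.librarian import (
    LIBRARY_CDR3_RANGES,
    LibraryDesign,
    PositionFrequencyMatrix,
    compute_pfm,
    design_from_annotations,
    export_logo_matrix,
    germline_accuracy,
    read_logo_matrix,
    stratify_cdr3,
    synthesize_library,
)
from nanolibkit.numbering import extract_regions, number_sequence
from nanolibkit.seqio import AMINO_ACIDS, SequenceRecord, validate_sequence
from nanolibkit.simdata import (
    RepertoireConfig,
    framework_annotation,
    seed_cdr3_profile,
    simulate_repertoire,
)


@pytest.fixture(scope="module")
def annotated(ref_by_name):
    out = {}
    for gi, (name, ref) in enumerate(sorted(ref_by_name.items())):
        records, _ = simulate_repertoire(
            RepertoireConfig(germline=name, n=250, seed=60 + gi)
        )
        out[name] = [extract_regions(number_sequence(r, ref)) for r in records]
    return out


def _point_mass_pfm(seq, germline="IGHV3-3*01", region="CDR3"):
    mat = np.zeros((len(seq), 20))
    for j, aa in enumerate(seq):
        mat[j, AMINO_ACIDS.index(aa)] = 1.0
    return PositionFrequencyMatrix(
        germline=germline, region=region, length_stratum=len(seq), matrix=mat,
        support=1,
    )


class TestComputePfm:
    def test_single_sequence_gives_point_mass_columns(self, annotated):
        anns = annotated["IGHV3-3*01"][:1]
        pfm = compute_pfm(anns, "IGHV3-3*01", "CDR1", len(anns[0].cdr1))
        assert (pfm.matrix.max(axis=1) == 1.0).all()
        assert pfm.support == 1

    def test_half_half_column(self, annotated):
        base = annotated["IGHV3-3*01"][0]
        other_cdr3 = "A" + base.cdr3[1:] if base.cdr3[0] != "A" else "G" + base.cdr3[1:]
        import copy

        variant = copy.copy(base)
        variant.cdr3 = other_cdr3
        pfm = compute_pfm([base, variant], "IGHV3-3*01", "CDR3", len(base.cdr3))
        assert sorted(pfm.matrix[0][pfm.matrix[0] > 0]) == [0.5, 0.5]
        assert (pfm.matrix[1:].max(axis=1) == 1.0).all()

    def test_empty_stratum_raises_with_context(self, annotated):
        with pytest.raises(ValueError, match="length=99"):
            compute_pfm(annotated["IGHV3-3*01"], "IGHV3-3*01", "CDR3", 99)

    def test_recovery_of_generating_profile(self, annotated):
        """PFM frequencies from a large simulated stratum recover the
        simulator's CDR3 residue profile."""
        anns = annotated["IGHV3-3*01"]
        strata = stratify_cdr3(anns, "IGHV3-3*01")
        L, members = max(strata.items(), key=lambda kv: len(kv[1]))
        pfm = compute_pfm(members, "IGHV3-3*01", "CDR3", L)
        profile = seed_cdr3_profile("IGHV3-3*01")
        expected = np.array([profile.get(aa, 0.0) for aa in AMINO_ACIDS])
        # pooled over columns the empirical frequencies approach the profile
        pooled = pfm.matrix.mean(axis=0)
        assert np.abs(pooled - expected).sum() <= 0.15


class TestStratifyCdr3:
    def test_single_stratum_when_all_lengths_equal(self, annotated):
        anns = [a for a in annotated["IGHV3-3*01"] if len(a.cdr3) == 17]
        strata = stratify_cdr3(anns, "IGHV3-3*01", (15, 19))
        assert set(strata) == {17}
        assert len(strata[17]) == len(anns)

    def test_out_of_range_lengths_dropped(self, annotated):
        anns = annotated["IGHV3S53*01"]
        strata = stratify_cdr3(anns, "IGHV3S53*01", (12, 16))
        assert all(12 <= L <= 16 for L in strata)

    def test_counts_match_simulator_draw_log(self, ref_by_name):
        records, truth = simulate_repertoire(
            RepertoireConfig(germline="IGHV3S53*01", n=120, seed=77)
        )
        ref = ref_by_name["IGHV3S53*01"]
        anns = [extract_regions(number_sequence(r, ref)) for r in records]
        strata = stratify_cdr3(anns, "IGHV3S53*01")
        expected = {}
        for t in truth:
            expected[len(t.cdr3)] = expected.get(len(t.cdr3), 0) + 1
        lo, hi = LIBRARY_CDR3_RANGES["IGHV3S53*01"]
        assert {L: len(v) for L, v in strata.items()} == {
            L: c for L, c in expected.items() if lo <= L <= hi
        }


class TestLogoExport:
    def test_point_mass_information_content(self, tmp_path):
        pfm = _point_mass_pfm("GYSSG")
        ic = pfm.information_content()
        assert ic == pytest.approx(np.full(5, math.log2(20)))

    def test_uniform_column_information_content_zero(self):
        mat = np.full((3, 20), 1 / 20)
        pfm = PositionFrequencyMatrix(
            germline="IGHV3-3*01", region="CDR3", length_stratum=3, matrix=mat,
            support=1,
        )
        assert pfm.information_content() == pytest.approx(np.zeros(3), abs=1e-12)

    def test_tsv_roundtrip_to_six_decimals(self, tmp_path, annotated):
        anns = annotated["IGHV3S53*01"]
        strata = stratify_cdr3(anns, "IGHV3S53*01")
        L = next(iter(strata))
        pfm = compute_pfm(strata[L], "IGHV3S53*01", "CDR3", L)
        path = tmp_path / "logo.tsv"
        export_logo_matrix(pfm, path)
        back = read_logo_matrix(path)
        assert np.abs(back - pfm.matrix).max() < 1e-6


class TestSynthesizeLibrary:
    def test_point_mass_design_yields_one_unique_member(self):
        fw = framework_annotation("IGHV3-3*01")
        design = LibraryDesign(
            germline="IGHV3-3*01",
            framework=fw,
            cdr1_pfm=_point_mass_pfm(fw.cdr1, region="CDR1"),
            cdr2_pfm=_point_mass_pfm(fw.cdr2, region="CDR2"),
            cdr3_pfms=[_point_mass_pfm(fw.cdr3, region="CDR3")],
        )
        with pytest.warns(UserWarning, match="diversity"):
            library = synthesize_library(design, n=5, seed=0)
        assert len(library) == 1
        assert library[0].seq == fw.seq

    def test_members_valid_unique_annotatable_and_assigned_home(
        self, annotated, references, ref_by_name
    ):
        design = design_from_annotations(
            "IGHV3-3*01",
            framework_annotation("IGHV3-3*01"),
            annotated["IGHV3-3*01"],
        )
        library = synthesize_library(design, n=300, seed=1)
        assert len(library) == 300
        assert len({r.seq for r in library}) == 300
        ref = ref_by_name["IGHV3-3*01"]
        for rec in library[:50]:
            assert validate_sequence(rec.seq).ok
            ann = extract_regions(number_sequence(rec, ref))
            assert len(ann.cdr1) == design.cdr1_pfm.length_stratum
        assert germline_accuracy(library[:100], "IGHV3-3*01", references) == 1.0

    def test_library_frequencies_match_design(self, annotated):
        """Column-wise chi-square between the design PFM and synthesized
        library counts shows no significant deviation at alpha=0.001."""
        from scipy import stats

        strata = stratify_cdr3(annotated["IGHV3-3*01"], "IGHV3-3*01")
        L, members = max(strata.items(), key=lambda kv: len(kv[1]))
        design = design_from_annotations(
            "IGHV3-3*01",
            framework_annotation("IGHV3-3*01"),
            members,
            length_range=(L, L),
        )
        library = synthesize_library(design, n=3000, seed=2)
        fw = design.framework
        # single CDR3 stratum: member layout is fixed, so the sampled CDR3
        # sits at a known offset
        start = (
            len(fw.region_seq("FR1")) + design.cdr1_pfm.length_stratum
            + len(fw.region_seq("FR2")) + design.cdr2_pfm.length_stratum
            + len(fw.region_seq("FR3"))
        )
        cdr3s = [rec.seq[start:start + L] for rec in library]
        pfm = design.cdr3_pfms[0]
        n = len(cdr3s)
        for j in range(L):
            observed = np.zeros(20)
            for s in cdr3s:
                observed[AMINO_ACIDS.index(s[j])] += 1
            expected = pfm.matrix[j] * n
            keep = expected >= 5  # chi-square validity: pool rare cells
            if keep.sum() < 2:
                continue
            obs = np.append(observed[keep], observed[~keep].sum())
            exp = np.append(expected[keep], expected[~keep].sum())
            if exp[-1] == 0:
                obs, exp = obs[:-1], exp[:-1]
            exp *= obs.sum() / exp.sum()
            p = stats.chisquare(obs, exp).pvalue
            assert p > 0.001, f"column {j} deviates (p={p:.2e})"

    def test_reproducible_from_seed(self, annotated):
        design = design_from_annotations(
            "IGHV3S53*01",
            framework_annotation("IGHV3S53*01"),
            annotated["IGHV3S53*01"],
        )
        a = synthesize_library(design, n=50, seed=7)
        b = synthesize_library(design, n=50, seed=7)
        assert [r.seq for r in a] == [r.seq for r in b]


class TestGermlineAccuracy:
    def test_reference_sequences_score_one(self, references):
        recs = [
            SequenceRecord(id=f"r{i}", seq=references[0].seq) for i in range(4)
        ]
        assert germline_accuracy(recs, references[0].name, references) == 1.0

    def test_half_half_mixture_scores_half(self, frameworks, references):
        fw1 = frameworks["IGHV3-3*01"]
        fw2 = frameworks["IGHV3S53*01"]
        recs = [
            SequenceRecord(id="a", seq=fw1.seq),
            SequenceRecord(id="b", seq=fw2.seq),
        ]
        assert germline_accuracy(recs, "IGHV3-3*01", references) == 0.5

    def test_empty_list_rejected(self, references):
        with pytest.raises(ValueError):
            germline_accuracy([], "IGHV3-3*01", references)
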