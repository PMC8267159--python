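import numpy as np
import pytest
from helpers import stats, va

from mratlas.errors import (
    DuplicateVariantError,
    FormatError,
    HarmonizationError,
    NoInstrumentsError,
)
from mratlas.estimators import ivw, mr_egger, weighted_median
from mratlas.summary_data import (
    HarmonizedInstrumentSet,
    LDMatrix,
    harmonize,
    ld_clump,
    read_ld_matrix,
    read_summary_tsv,
    select_instruments,
    write_summary_tsv,
)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _write(tmp_path, text, name="stats.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"


def test_read_well_formed(tmp_path):
    p = _write(
        tmp_path,
        HEADER + "\n"
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-10\t5000\n"
        "rs2\t2\t200\tC\tT\tNA\t-0.2\t0.02\t1e-9\tNA\n"
        "rs3\t3\t300\tG\tA\t0.5\t0.05\t0.01\t0.5\t5000\n",
    )
    s = read_summary_tsv(p, trait_name="t")
    assert len(s) == 3
    assert s.records[1].eaf is None and s.records[1].n is None
    assert s.records[1].beta == -0.2


def test_row_with_zero_se_rejected(tmp_path):
    p = _write(
        tmp_path,
        HEADER + "\n"
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.0\t1e-10\t5000\n"
        "rs2\t1\t200\tA\tG\t0.3\t0.1\t0.01\t1e-10\t5000\n",
    )
    s = read_summary_tsv(p)
    assert len(s) == 1
    assert len(s.rejected) == 1
    assert "se" in s.rejected[0][1]


def test_non_numeric_beta_rejected(tmp_path):
    p = _write(
        tmp_path,
        HEADER + "\nrs1\t1\t100\tA\tG\t0.3\toops\t0.01\t1e-10\t5000\n",
    )
    with pytest.raises(NoInstrumentsError):
        # nothing retained -> selection must refuse
        select_instruments(read_summary_tsv(p), 1.0)


def test_missing_column_is_format_error(tmp_path):
    p = _write(tmp_path, "variant_id\tbeta\nrs1\t0.1\n")
    with pytest.raises(FormatError, match="missing required column"):
        read_summary_tsv(p)


def test_duplicate_variant_id_names_the_id(tmp_path):
    p = _write(
        tmp_path,
        HEADER + "\n"
        "rs7\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-10\t5000\n"
        "rs7\t1\t200\tA\tG\t0.3\t0.1\t0.01\t1e-10\t5000\n",
    )
    with pytest.raises(DuplicateVariantError, match="rs7"):
        read_summary_tsv(p)


def test_round_trip(tmp_path):
    original = stats(
        "t",
        [
            va("rs1", beta=0.123456789012345, se=0.01, pval=1e-10),
            va("rs2", ea="C", oa="T", eaf=None, n=None, pval=0.25),
        ],
    )
    p = tmp_path / "rt.tsv"
    write_summary_tsv(original, p)
    again = read_summary_tsv(p, trait_name="t")
    assert again == original


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------


def test_select_instruments_strict_threshold():
    s = stats(
        "t",
        [va("a", pval=1e-9), va("b", pval=4e-8), va("c", pval=6e-8)],
    )
    kept = select_instruments(s, 5e-8)
    assert kept.variant_ids == ["a", "b"]
    assert len(s) == 3  # input untouched


def test_select_instruments_threshold_one_keeps_all():
    s = stats("t", [va("a", pval=0.9), va("b", pval=0.5)])
    assert len(select_instruments(s, 1.0)) == 2


def test_select_instruments_empty_raises():
    s = stats("t", [va("a", pval=0.9)])
    with pytest.raises(NoInstrumentsError):
        select_instruments(s, 5e-8)


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------


def _ld(ids, mat, positions=None):
    return LDMatrix(list(ids), np.asarray(mat, dtype=float), positions=positions)


def test_clump_dominated_pair():
    s = stats(
        "t",
        [
            va("a", pos=1_000_000, pval=1e-10),
            va("b", pos=1_005_000, pval=1e-9),
        ],
    )
    ld = _ld(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
    kept = ld_clump(s, ld)
    assert kept.variant_ids == ["a"]


def test_clump_independent_pair_both_kept():
    s = stats(
        "t",
        [va("a", pos=1_000_000, pval=1e-10), va("b", pos=1_005_000, pval=1e-9)],
    )
    ld = _ld(["a", "b"], [[1.0, 0.0], [0.0, 1.0]])
    assert len(ld_clump(s, ld)) == 2


def test_clump_five_snp_hand_trace():
    # Hand-executed greedy trace. All SNPs on chrom 1 within the window.
    # p order: s1 < s2 < s3 < s4 < s5.
    #   keep s1 -> discards s2 (r2 .5) and s5 (r2 .3); s3 (.0005) and s4 (0) stay
    #   keep s3 -> discards s4 (r2 .2)
    # kept set: {s1, s3}, ordered by p.
    ids = ["s1", "s2", "s3", "s4", "s5"]
    r2 = np.array(
        [
            [1.0, 0.5, 0.0005, 0.0, 0.3],
            [0.5, 1.0, 0.1, 0.0, 0.2],
            [0.0005, 0.1, 1.0, 0.2, 0.0],
            [0.0, 0.0, 0.2, 1.0, 0.0],
            [0.3, 0.2, 0.0, 0.0, 1.0],
        ]
    )
    s = stats(
        "t",
        [
            va("s1", pos=1_000_000, pval=1e-20),
            va("s2", pos=2_000_000, pval=1e-15),
            va("s3", pos=3_000_000, pval=1e-12),
            va("s4", pos=4_000_000, pval=1e-10),
            va("s5", pos=5_000_000, pval=1e-8),
        ],
    )
    kept = ld_clump(s, _ld(ids, r2))
    assert kept.variant_ids == ["s1", "s3"]


def test_clump_far_apart_high_r2_kept():
    # same chromosome but outside the window -> distance rule wins
    s = stats(
        "t",
        [va("a", pos=1_000_000, pval=1e-10), va("b", pos=20_000_000, pval=1e-9)],
    )
    ld = _ld(["a", "b"], [[1.0, 0.9], [0.9, 1.0]])
    assert len(ld_clump(s, ld)) == 2


def test_clump_missing_variant_treated_independent(caplog):
    s = stats(
        "t",
        [va("a", pos=1_000_000, pval=1e-10), va("b", pos=1_005_000, pval=1e-9)],
    )
    ld = _ld(["a"], [[1.0]])
    with caplog.at_level("WARNING"):
        kept = ld_clump(s, ld)
    assert len(kept) == 2
    assert any("independent" in r.message for r in caplog.records)


def test_clump_tie_break_lexicographic():
    s = stats(
        "t",
        [va("zzz", pos=1_000_000, pval=1e-10), va("aaa", pos=1_005_000, pval=1e-10)],
    )
    ld = _ld(["aaa", "zzz"], [[1.0, 0.9], [0.9, 1.0]])
    assert ld_clump(s, ld).variant_ids == ["aaa"]


def test_clump_subset_and_pairwise_property():
    # randomized fixture; retained set must satisfy the pairwise constraint
    rng = np.random.default_rng(7)
    n = 12
    a = rng.uniform(0, 1, size=(n, n))
    r2 = (a + a.T) / 2
    np.fill_diagonal(r2, 1.0)
    ids = [f"v{i}" for i in range(n)]
    recs = [
        va(ids[i], pos=1_000_000 + i * 500_000, pval=float(rng.uniform(1e-12, 1e-6)))
        for i in range(n)
    ]
    s = stats("t", recs)
    ld = _ld(ids, r2)
    kept = ld_clump(s, ld, r2_max=0.3, window_kb=2_000)
    assert set(kept.variant_ids) <= set(s.variant_ids)
    by_id = s.by_id()
    for i, vi in enumerate(kept.variant_ids):
        for vj in kept.variant_ids[i + 1 :]:
            ri, rj = by_id[vi], by_id[vj]
            if ri.chrom == rj.chrom and abs(ri.pos - rj.pos) <= 2_000_000:
                assert ld.r2_between(vi, vj) <= 0.3


def test_read_ld_matrix_long_format(tmp_path):
    p = tmp_path / "ld.tsv"
    p.write_text("id_a\tid_b\tr2\na\tb\t0.5\n")
    ld = read_ld_matrix(p)
    assert ld.r2_between("a", "b") == 0.5
    assert ld.r2_between("a", "a") == 1.0


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def test_harmonize_swap_and_flip():
    exposure = stats("x", [va("rs1", ea="A", oa="G", beta=0.1)])
    outcome = stats("y", [va("rs1", ea="G", oa="A", beta=-0.05, eaf=0.7)])
    h = harmonize(exposure, outcome)
    assert h.Gamma[0] == pytest.approx(0.05)
    assert h.effect_allele == ["A"]
    assert bool(h.flipped[0])


def test_harmonize_identical_is_noop():
    exposure = stats("x", [va("rs1", beta=0.1), va("rs2", ea="C", oa="T", beta=0.2)])
    outcome = stats("y", [va("rs1", beta=0.03), va("rs2", ea="C", oa="T", beta=0.07)])
    h = harmonize(exposure, outcome)
    assert list(h.Gamma) == [0.03, 0.07]
    assert not h.flipped.any()
    assert h.dropped == []


def test_harmonize_palindromic_concordant_kept():
    exposure = stats("x", [va("rs1", ea="A", oa="T", eaf=0.10)])
    outcome = stats("y", [va("rs1", ea="A", oa="T", eaf=0.12, beta=0.04)])
    h = harmonize(exposure, outcome)
    assert h.Gamma[0] == pytest.approx(0.04)
    assert bool(h.palindromic[0]) and not bool(h.flipped[0])


def test_harmonize_palindromic_discordant_flipped():
    exposure = stats("x", [va("rs1", ea="C", oa="G", eaf=0.10)])
    outcome = stats("y", [va("rs1", ea="C", oa="G", eaf=0.88, beta=0.04)])
    h = harmonize(exposure, outcome)
    assert h.Gamma[0] == pytest.approx(-0.04)
    assert bool(h.flipped[0])


@pytest.mark.parametrize("eaf_out", [0.42, 0.5, 0.58])
def test_harmonize_palindromic_ambiguous_dropped(eaf_out):
    exposure = stats(
        "x", [va("rs1", ea="A", oa="T", eaf=0.10), va("rs2", beta=0.2)]
    )
    outcome = stats(
        "y", [va("rs1", ea="A", oa="T", eaf=eaf_out), va("rs2", beta=0.05)]
    )
    h = harmonize(exposure, outcome)
    assert h.variant_ids == ["rs2"]
    assert h.dropped == [("rs1", "palindromic, eaf in ambiguity band")]


def test_harmonize_strand_complement_resolved():
    exposure = stats("x", [va("rs1", ea="A", oa="G", beta=0.1)])
    outcome = stats("y", [va("rs1", ea="T", oa="C", beta=0.05)])
    h = harmonize(exposure, outcome)
    assert h.Gamma[0] == pytest.approx(0.05)
    assert not bool(h.flipped[0])


def test_harmonize_irreconcilable_dropped():
    exposure = stats("x", [va("rs1", ea="A", oa="G"), va("rs2", beta=0.2)])
    outcome = stats("y", [va("rs1", ea="A", oa="C"), va("rs2", beta=0.05)])
    h = harmonize(exposure, outcome)
    assert h.variant_ids == ["rs2"]
    assert h.dropped[0] == ("rs1", "irreconcilable alleles")


def test_harmonize_no_shared_variants():
    with pytest.raises(HarmonizationError):
        harmonize(stats("x", [va("rs1")]), stats("y", [va("rs2")]))


def test_harmonize_involution():
    exposure = stats("x", [va("rs1", beta=0.1), va("rs2", ea="T", oa="C", beta=0.2)])
    outcome = stats("y", [va("rs1", beta=0.03), va("rs2", ea="T", oa="C", beta=0.07)])
    h1 = harmonize(exposure, outcome)
    h2 = harmonize(exposure, outcome)
    assert h1 == h2
    assert not h1.flipped.any()


def test_estimators_invariant_under_joint_sign_flips():
    rng = np.random.default_rng(11)
    j = 8
    gamma = rng.uniform(0.05, 0.2, j)
    Gamma = 0.3 * gamma + rng.normal(0, 0.01, j)
    se_y = np.full(j, 0.01)
    se_x = np.full(j, 0.005)
    h = HarmonizedInstrumentSet.from_arrays(gamma, Gamma, se_y, se_x)
    flip = rng.choice([1.0, -1.0], j)
    h_flipped = HarmonizedInstrumentSet.from_arrays(
        gamma * flip, Gamma * flip, se_y, se_x
    )
    assert ivw(h).beta == pytest.approx(ivw(h_flipped).beta, rel=1e-12)
    assert mr_egger(h).beta == pytest.approx(mr_egger(h_flipped).beta, rel=1e-12)
    wm1 = weighted_median(h, seed=1)
    wm2 = weighted_median(h_flipped, seed=1)
    assert wm1.beta == pytest.approx(wm2.beta, rel=1e-12)
    assert wm1.se == pytest.approx(wm2.se, rel=1e-12)  # oriented before bootstrap
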