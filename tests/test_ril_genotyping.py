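"""HMM haploblocks vs exhaustive enumeration; distortion scan; co-segregation."""

import io

import numpy as np
import pandas as pd
import pytest

from rdnapanel import ril_genotyping as rg
from rdnapanel import synthetic_data as sd


def make_gm(call_rows, positions_bp, cm=None, epsilon=0.01, chrom="I"):
    positions_bp = np.asarray(positions_bp)
    if cm is None:
        cm = np.linspace(0.0, 50.0, len(positions_bp))
    mm = pd.DataFrame(
        {
            "marker": [f"{chrom}:{p}" for p in positions_bp],
            "chrom": chrom,
            "pos_bp": positions_bp,
            "pos_cm": cm,
        }
    )
    calls = pd.DataFrame(
        call_rows, index=[f"L{i}" for i in range(len(call_rows))], columns=mm["marker"]
    )
    return rg.GenotypeMatrix(calls=calls, marker_map=mm, epsilon=epsilon)


def enumerate_posteriors(obs, r, epsilon):
    """Independent oracle: sum over all 2^n hidden paths."""
    n = len(obs)
    emis = np.ones((n, 2))
    for i, o in enumerate(obs):
        if o == "A":
            emis[i] = (1 - epsilon, epsilon)
        elif o == "B":
            emis[i] = (epsilon, 1 - epsilon)
    post = np.zeros((n, 2))
    total = 0.0
    for bits in range(2 ** n):
        path = [(bits >> i) & 1 for i in range(n)]
        p = 0.5 * emis[0][path[0]]
        for i in range(1, n):
            p *= (r[i - 1] if path[i] != path[i - 1] else 1 - r[i - 1]) * emis[i][path[i]]
        total += p
        for i in range(n):
            post[i, path[i]] += p
    return post / total


class TestHmmOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_posteriors_match_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        obs = rng.choice(["A", "B", "H", "N"], size=n, p=[0.4, 0.4, 0.1, 0.1])
        cm = np.cumsum(rng.uniform(0.5, 15.0, size=n))
        eps = float(rng.uniform(0.005, 0.2))
        gm = make_gm([list(obs)], np.arange(1, n + 1) * 10_000, cm=cm, epsilon=eps)
        hbs = rg.call_haploblocks(gm)
        r = rg.haldane(np.diff(cm))
        expected = enumerate_posteriors(obs, r, eps)
        np.testing.assert_allclose(hbs.posteriors[("L0", "I")], expected, atol=1e-10)

    def test_uniform_evidence_single_confident_block(self):
        gm = make_gm([["A"] * 30], np.arange(1, 31) * 100_000, epsilon=0.01)
        hbs = rg.call_haploblocks(gm)
        blocks = hbs.blocks_for("L0", "I")
        assert len(blocks) == 1 and blocks.loc[0, "label"] == "A"
        assert (hbs.posteriors[("L0", "I")][:, 0] > 0.99).all()

    def test_single_breakpoint_decoding_accuracy(self):
        rng = np.random.default_rng(5)
        n = 200
        truth = np.array(["A"] * 100 + ["B"] * 100)
        correct = []
        for _ in range(20):
            obs = truth.copy()
            flips = rng.random(n) < 0.01
            obs[flips] = np.where(truth[flips] == "A", "B", "A")
            gm = make_gm([list(obs)], np.arange(1, n + 1) * 50_000, epsilon=0.01)
            hbs = rg.call_haploblocks(gm)
            labels = hbs.labels_for("L0", "I")
            correct.append(np.mean(labels == truth))
        assert np.mean(correct) >= 0.99

    def test_accuracy_monotone_in_error_rate(self):
        n = 300
        truth = np.array((["A"] * 75 + ["B"] * 75) * 2)
        accs = []
        for eps in (0.0, 0.01, 0.05, 0.2):
            rng = np.random.default_rng(99)  # same truth, same flip positions
            acc = []
            for _ in range(30):
                obs = truth.copy()
                flips = rng.random(n) < eps
                obs[flips] = np.where(truth[flips] == "A", "B", "A")
                gm = make_gm([list(obs)], np.arange(1, n + 1) * 30_000,
                             epsilon=max(eps, 1e-3))
                labels = rg.call_haploblocks(gm).labels_for("L0", "I")
                acc.append(np.mean(labels == truth))
            accs.append(np.mean(acc))
        assert all(a >= b - 0.005 for a, b in zip(accs, accs[1:]))

    def test_all_missing_chromosome_warns_single_block(self):
        gm = make_gm([["N"] * 10], np.arange(1, 11) * 10_000)
        with pytest.warns(UserWarning, match="no informative calls"):
            hbs = rg.call_haploblocks(gm, chrom_lengths={"I": 1_000_000})
        blocks = hbs.blocks_for("L0", "I")
        assert len(blocks) == 1
        assert blocks.loc[0, "start"] == 0 and blocks.loc[0, "end"] == 1_000_000
        assert blocks.loc[0, "label"] == "A"  # uniform-prior tie rule

    def test_blocks_tile_chromosome_with_midpoint_breakpoints(self):
        obs = ["A"] * 5 + ["B"] * 5
        pos = np.arange(1, 11) * 100_000
        gm = make_gm([obs], pos)
        hbs = rg.call_haploblocks(gm, chrom_lengths={"I": 2_000_000})
        blocks = hbs.blocks_for("L0", "I")
        assert blocks.loc[0, "start"] == 0
        assert blocks.iloc[-1]["end"] == 2_000_000
        assert (blocks["end"].to_numpy()[:-1] == blocks["start"].to_numpy()[1:]).all()
        assert blocks.loc[0, "end"] == (pos[4] + pos[5]) // 2


class TestDistortionScan:
    def test_perfect_balance_not_flagged(self):
        gm = make_gm([["A"], ["B"]] * 30, [1000], epsilon=0.01)
        scan = rg.scan_segregation_distortion(gm)
        assert scan.table.loc[0, "p_value"] == pytest.approx(1.0)
        assert not scan.table.loc[0, "flagged"]

    def test_total_distortion_closed_form(self):
        gm = make_gm([["A"]] * 60, [1000], epsilon=0.01)
        scan = rg.scan_segregation_distortion(gm)
        assert scan.table.loc[0, "p_value"] == pytest.approx(2 * 0.5**60, rel=1e-9)
        assert scan.table.loc[0, "flagged"]

    def test_uninformative_marker_excluded(self):
        rows = [["A", "N"], ["B", "N"], ["A", "H"]]
        gm = make_gm(rows, [1000, 2000], epsilon=0.01)
        scan = rg.scan_segregation_distortion(gm)
        assert scan.excluded_markers == ["I:2000"]
        assert scan.n_tested == 1

    def test_selection_signal_localizes_to_incompatibility_locus(self, small_genome):
        cfg = sd.PanelConfig(n_lines=118, selfing_generations=6, seed=17)
        panel = sd.simulate_ril_panel(cfg, small_genome)
        gm = sd.simulate_genotype_matrix(
            panel, small_genome, rng=np.random.default_rng(17)
        )
        scan = rg.scan_segregation_distortion(gm)
        flagged = scan.table[scan.table["flagged"]]
        assert len(flagged) > 0
        assert (flagged["chrom"] == "I").all()
        assert abs(flagged["pos_bp"].median() - 2_300_000) < 1_500_000


class TestCosegregation:
    def test_perfect_cosegregation(self):
        tg = [True] * 58 + [False] * 60
        ac = ["LOW"] * 58 + ["HIGH"] * 60
        res = rg.test_cosegregation(tg, ac)
        assert res.concordance == 1.0
        assert res.table.loc[True, "LOW"] == 58
        assert res.table.loc[False, "HIGH"] == 60

    def test_one_discordant_line(self):
        tg = [True] * 58 + [False] * 60
        ac = ["LOW"] * 57 + ["HIGH"] * 61
        res = rg.test_cosegregation(tg, ac)
        assert res.concordance == pytest.approx(117 / 118)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rg.test_cosegregation([True], ["LOW", "HIGH"])


class TestPrivateVariants:
    def test_published_table_yields_four_my1_only_variants(self):
        assert rg.count_private_variants() == 4

    def test_custom_table_collapsing_and_exclusion(self):
        df = pd.DataFrame(
            {
                "gene": ["g1", "g1", "g2", "g3"],
                "amino_acid": ["x", "y", "z", "w"],
                "pos_bp": [100, 100, 200, 300],
                "isolates": ["MY1", "MY1", "MY1, RC301", "RC301"],
            }
        )
        assert rg.count_private_variants(df) == 1
        assert rg.count_private_variants(df, isolate="RC301",
                                         exclude_shared_with="MY1") == 1


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=I,length=15072434>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tRIL001
I\t1000\t.\tA\tG\t60\tPASS\t.\tGT\t0/0
I\t2000\t.\tC\tT\t60\tPASS\t.\tGT\t1/1
I\t3000\t.\tG\tA\t60\tPASS\t.\tGT\t0/1
I\t4000\t.\tT\tC\t60\tPASS\t.\tGT\t./.
I\t5000\t.\tA\tC,G\t60\tPASS\t.\tGT\t1/1
"""


def test_vcf_ingestion(tmp_path):
    path = tmp_path / "line.vcf"
    path.write_text(VCF_TEXT)
    calls = rg.genotype_calls_from_vcf(path)
    assert calls["call"].tolist() == ["A", "B", "H", "N"]  # multiallelic skipped
    assert calls["pos_bp"].tolist() == [1000, 2000, 3000, 4000]
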