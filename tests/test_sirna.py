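"""siRNA-screen scoring: percent inhibition, GARP, HSA, matrix and consensus."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atomi.exceptions import (
    ConfigurationError,
    FormatError,
    IncompleteGeneError,
    MissingControlError,
    PlateQCError,
)
from atomi.sirna import (
    DoseMatrix,
    PlateControls,
    consensus_hits,
    export_network_table,
    garp,
    hsa_synergy,
    matrix_hsa,
    percent_inhibition,
    plate_controls,
    score_screen,
)
from conftest import make_controls_wells

finite = st.floats(-100, 200, allow_nan=False)


def ctrl(neg=1000.0, pos=100.0):
    return PlateControls(average_neg=neg, average_pos=pos, n_neg=2, n_pos=1)


class TestPlateControls:
    def test_means_pool_both_negative_types(self):
        wells = pd.DataFrame(
            [
                dict(plate_id="P", well_id="a", target="NEG_SCRAMBLED", sirna_id=0,
                     arm="VEHICLE", viability=900.0),
                dict(plate_id="P", well_id="b", target="NEG_ALLSTARS", sirna_id=0,
                     arm="VEHICLE", viability=1100.0),
                dict(plate_id="P", well_id="c", target="POS_DEATH", sirna_id=0,
                     arm="VEHICLE", viability=90.0),
                dict(plate_id="P", well_id="d", target="POS_DEATH", sirna_id=0,
                     arm="VEHICLE", viability=110.0),
            ]
        )
        c = plate_controls(wells)
        assert (c.average_neg, c.average_pos) == (1000.0, 100.0)
        assert (c.n_neg, c.n_pos) == (2, 2)

    def test_inverted_controls_fail_qc(self):
        wells = pd.DataFrame(
            [
                dict(plate_id="P9", well_id="a", target="NEG_SCRAMBLED", sirna_id=0,
                     arm="VEHICLE", viability=100.0),
                dict(plate_id="P9", well_id="b", target="POS_DEATH", sirna_id=0,
                     arm="VEHICLE", viability=1000.0),
            ]
        )
        with pytest.raises(PlateQCError, match="P9"):
            plate_controls(wells, plate_id="P9")

    def test_missing_control_class_names_plate(self):
        wells = pd.DataFrame(
            [dict(plate_id="P7", well_id="a", target="NEG_SCRAMBLED", sirna_id=0,
                  arm="VEHICLE", viability=100.0)]
        )
        with pytest.raises(MissingControlError, match="P7"):
            plate_controls(wells, plate_id="P7")


class TestPercentInhibition:
    @pytest.mark.parametrize(
        "sample,expected",
        [(1000.0, 0.0), (100.0, 100.0), (550.0, 50.0), (1090.0, -10.0)],
    )
    def test_printed_formula(self, sample, expected):
        assert percent_inhibition(sample, ctrl()) == pytest.approx(expected)

    @given(st.floats(0, 2000), st.floats(1e-2, 1e3))
    @settings(derandomize=True, max_examples=50)
    def test_affine_scale_invariance(self, sample, c):
        base = percent_inhibition(sample, ctrl())
        scaled = percent_inhibition(c * sample, ctrl(1000.0 * c, 100.0 * c))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    @given(st.floats(0, 2000), st.floats(0, 2000))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_sample(self, a, b):
        if abs(a - b) < 1e-6:
            return
        lo, hi = sorted((a, b))
        assert percent_inhibition(lo, ctrl()) > percent_inhibition(hi, ctrl())


class TestGarp:
    @pytest.mark.parametrize(
        "vals,expected",
        [([10, 20, 30], 25.0), ([40, 40, 40], 40.0), ([-5, 0, 80], 40.0)],
    )
    def test_mean_of_two_highest(self, vals, expected):
        assert garp(vals) == pytest.approx(expected)

    def test_wrong_arity_flagged_incomplete(self):
        with pytest.raises(IncompleteGeneError):
            garp([10, 20])

    @given(st.lists(finite, min_size=3, max_size=3))
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariant_and_bounded(self, vals):
        scores = {garp(p) for p in ([vals[i] for i in order] for order in
                                    [(0, 1, 2), (2, 0, 1), (1, 2, 0), (2, 1, 0)])}
        assert len(scores) == 1
        g = garp(vals)
        assert np.median(vals) - 1e-9 <= g <= max(vals) + 1e-9

    @given(st.lists(finite, min_size=3, max_size=3), st.floats(0, 50))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_each_input(self, vals, bump):
        g = garp(vals)
        for i in range(3):
            up = list(vals)
            up[i] += bump
            assert garp(up) >= g - 1e-9


class TestHsaSynergy:
    @pytest.mark.parametrize(
        "combo,a,b,expected",
        [(70, 40, 30, 30.0), (40, 40, 30, 0.0), (25, 40, 10, -15.0)],
    )
    def test_excess_over_best_single(self, combo, a, b, expected):
        assert hsa_synergy(combo, a, b) == pytest.approx(expected)

    @given(finite, finite, finite)
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_and_null(self, combo, a, b):
        assert hsa_synergy(combo, a, b) == hsa_synergy(combo, b, a)
        assert hsa_synergy(max(a, b), a, b) == pytest.approx(0.0)


class TestDoseMatrix:
    def matrix(self, resp, a=(0, 1, 2), b=(0, 1, 2)):
        return DoseMatrix(tuple(a), tuple(b), np.asarray(resp, dtype=float))

    def test_hsa_null_surface_gives_zero(self):
        single_a, single_b = [0, 20, 40], [0, 10, 50]
        resp = [[max(sa, sb) for sb in single_b] for sa in single_a]
        table, summary = matrix_hsa(self.matrix(resp))
        assert summary == pytest.approx(0.0)
        assert np.allclose(table.to_numpy(), 0.0)

    def test_uniform_excess(self):
        resp = [[0, 10, 50], [20, 30, 60], [40, 50, 60]]
        # inner = max(single) + 10 everywhere
        table, summary = matrix_hsa(self.matrix(resp))
        assert summary == pytest.approx(10.0)

    def test_random_matrices_match_double_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            resp = rng.uniform(-20, 100, size=(k, k))
            resp[0, 0] = 0.0
            doses = tuple(np.concatenate([[0.0], np.sort(rng.uniform(0.1, 10, k - 1))]))
            table, summary = matrix_hsa(DoseMatrix(doses, doses, resp))
            acc = []
            for i in range(1, k):
                for j in range(1, k):
                    acc.append(resp[i, j] - max(resp[i, 0], resp[0, j]))
            assert summary == pytest.approx(np.mean(acc))

    def test_transpose_invariance_of_summary(self):
        rng = np.random.default_rng(9)
        resp = rng.uniform(0, 80, size=(4, 5))
        resp[0, 0] = 0.0
        a, b = (0.0, 1.0, 2.0, 4.0), (0.0, 0.5, 1.0, 2.0, 4.0)
        _, s1 = matrix_hsa(DoseMatrix(a, b, resp))
        _, s2 = matrix_hsa(DoseMatrix(b, a, resp.T))
        assert s1 == pytest.approx(s2)

    @pytest.mark.parametrize(
        "a,b,resp",
        [
            ((0, 2, 1), (0, 1), np.zeros((3, 2))),      # non-monotone doses
            ((1, 2), (0, 1), np.zeros((2, 2))),          # missing zero dose
            ((0, 1), (0, 1), [[5.0, 0], [0, 0]]),        # nonzero untreated cell
        ],
    )
    def test_malformed_matrices_rejected(self, a, b, resp):
        with pytest.raises(FormatError):
            DoseMatrix(tuple(a), tuple(b), np.asarray(resp, dtype=float))


def straight_line_scores(wells: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Independent spreadsheet-style recomputation of the screen scoring.

    Pools vehicle-arm controls for the anchor, applies the printed
    percent-inhibition formula to per-siRNA well means, takes the mean of the
    two highest values per gene and arm, and subtracts the larger single
    effect. Deliberately plain loops, no shared code with the package path.
    """
    neg = wells[(wells["arm"] == "VEHICLE")
                & wells["target"].isin(["NEG_SCRAMBLED", "NEG_ALLSTARS"])]
    pos = wells[(wells["arm"] == "VEHICLE") & (wells["target"] == "POS_DEATH")]
    avg_neg, avg_pos = neg["viability"].mean(), pos["viability"].mean()

    def pct(v):
        return 100.0 * (avg_neg - v) / (avg_neg - avg_pos)

    drug_wells = wells[(wells["arm"] == arm)
                       & wells["target"].isin(["NEG_SCRAMBLED", "NEG_ALLSTARS"])]
    single_drug = np.mean([pct(v) for v in drug_wells["viability"]])

    rows = []
    genes = sorted(
        set(wells["target"])
        - {"NEG_SCRAMBLED", "NEG_ALLSTARS", "POS_DEATH"}
    )
    for gene in genes:
        garps = {}
        for a in ("VEHICLE", arm):
            vals = []
            for s in (1, 2, 3):
                sub = wells[(wells["target"] == gene) & (wells["arm"] == a)
                            & (wells["sirna_id"] == s)]
                vals.append(np.mean([pct(v) for v in sub["viability"]]))
            vals.sort()
            garps[a] = (vals[1] + vals[2]) / 2.0
        rows.append(
            dict(gene=gene, garp_vehicle=garps["VEHICLE"], garp_arm=garps[arm],
                 single_drug_effect=single_drug,
                 synergy=garps[arm] - max(garps["VEHICLE"], single_drug))
        )
    return pd.DataFrame(rows)


def random_screen(rng, n_genes, arm="DRUG"):
    """A random two-arm screen table with arbitrary positive viabilities."""
    rows = []
    genes = [f"G{i}" for i in range(n_genes)]
    for a, plate in (("VEHICLE", "PV"), (arm, "PA")):
        w = iter(range(10_000))
        for gene in genes:
            for s in (1, 2, 3):
                rows.append(dict(plate_id=plate, well_id=f"w{next(w)}", target=gene,
                                 sirna_id=s, arm=a,
                                 viability=float(rng.uniform(100, 12000))))
        for label, base in (("NEG_SCRAMBLED", 10000), ("NEG_ALLSTARS", 10000),
                            ("POS_DEATH", 400)):
            for _ in range(3):
                rows.append(dict(plate_id=plate, well_id=f"w{next(w)}", target=label,
                                 sirna_id=0, arm=a,
                                 viability=float(base * rng.uniform(0.8, 1.2))))
    return pd.DataFrame(rows)


class TestScoreScreen:
    def test_noise_free_synergy_equals_planted(self, noise_free_screen):
        cfg, table, truth = noise_free_screen
        for arm in cfg.arms:
            scores, report = score_screen(table, arm)
            scores = scores.set_index("gene")
            for gene in cfg.genes:
                expected = cfg.synergy_effect if gene in truth.true_synergizers else 0.0
                assert scores.loc[gene, "synergy"] == pytest.approx(expected, abs=1e-9)
            assert report.single_drug_effect == pytest.approx(cfg.arm_effect(arm))

    def test_identical_arms_and_inert_drug_give_zero_synergy(self):
        rows = make_controls_wells("PV", "VEHICLE") + make_controls_wells("PA", "DRUG")
        for a, plate in (("VEHICLE", "PV"), ("DRUG", "PA")):
            for s in (1, 2, 3):
                rows.append(dict(plate_id=plate, well_id=f"g{s}", target="AKT1",
                                 sirna_id=s, arm=a, viability=8000.0))
        scores, report = score_screen(pd.DataFrame(rows), "DRUG")
        assert report.single_drug_effect == pytest.approx(0.0)
        assert scores.loc[0, "synergy"] == pytest.approx(0.0)

    def test_matches_straight_line_oracle_on_random_screens(self):
        rng = np.random.default_rng(2024)
        for rep in range(40):
            wells = random_screen(rng, int(rng.integers(2, 9)))
            got, _ = score_screen(wells, "DRUG")
            want = straight_line_scores(wells, "DRUG")
            merged = got.merge(want, on="gene", suffixes=("", "_oracle"))
            for col in ("garp_vehicle", "garp_arm", "single_drug_effect", "synergy"):
                np.testing.assert_allclose(
                    merged[col], merged[f"{col}_oracle"], rtol=1e-9, atol=1e-9
                )
            # ranking equals the oracle's ordering by synergy
            want_order = want.sort_values(["synergy", "gene"],
                                          ascending=[False, True])["gene"].tolist()
            assert got["gene"].tolist() == want_order

    def test_incomplete_gene_excluded_and_reported(self, noise_free_screen):
        cfg, table, truth = noise_free_screen
        broken = table[~((table["target"] == "KIN005") & (table["sirna_id"] == 3))]
        scores, report = score_screen(broken, "DRUG")
        assert "KIN005" in report.excluded_genes
        assert "KIN005" not in set(scores["gene"])

    def test_qc_failed_vehicle_plate_aborts(self, noise_free_screen):
        cfg, table, truth = noise_free_screen
        bad = table.copy()
        neg = bad["target"].isin(["NEG_SCRAMBLED", "NEG_ALLSTARS"])
        veh = bad["arm"] == "VEHICLE"
        bad.loc[neg & veh, "viability"] = 10.0  # controls inverted on the only vehicle plate
        with pytest.raises(MissingControlError):
            score_screen(bad, "DRUG")

    def test_unknown_arm_rejected(self, noise_free_screen):
        _, table, _ = noise_free_screen
        with pytest.raises(ConfigurationError):
            score_screen(table, "VEHICLE")

    def test_arm_anchoring_zeroes_combination_baseline(self, noise_free_screen):
        # under arm anchoring a gene whose knockdown is weaker than the drug
        # shows no extra effect in the combination arm
        cfg, table, truth = noise_free_screen
        scores, _ = score_screen(table, "DRUG", anchor="arm")
        scores = scores.set_index("gene")
        null_gene = next(g for g in cfg.genes if g not in truth.true_synergizers)
        assert scores.loc[null_gene, "garp_arm"] == pytest.approx(0.0, abs=1e-9)


class TestConsensus:
    def table(self, entries):
        return pd.DataFrame(
            [dict(gene=g, synergy=s, garp_vehicle=0, garp_arm=0,
                  single_drug_effect=0, rank=i + 1)
             for i, (g, s) in enumerate(entries)]
        )

    def test_requires_positive_synergy_in_both_arms(self):
        drug = self.table([("A", 20.0), ("B", 20.0), ("C", -1.0)])
        genetic = self.table([("A", 15.0), ("B", -3.0), ("C", 10.0)])
        genes, merged = consensus_hits(drug, genetic, min_synergy=0.0)
        assert genes == {"A"}
        assert set(merged["gene"]) == {"A", "B", "C"}

    def test_disjoint_universes_error(self):
        with pytest.raises(ConfigurationError):
            consensus_hits(self.table([("A", 1.0)]), self.table([("B", 1.0)]))

    def test_matches_brute_force_filter_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            genes = [f"G{i}" for i in range(10)]
            sd = {g: rng.uniform(-20, 40) for g in genes}
            sg = {g: rng.uniform(-20, 40) for g in genes}
            thr = float(rng.uniform(-5, 10))
            got, _ = consensus_hits(
                self.table(sd.items()), self.table(sg.items()), min_synergy=thr
            )
            want = {g for g in genes if sd[g] > thr and sg[g] > thr}
            assert got == want

    def test_network_table_round_trip(self, tmp_path):
        drug = self.table([("AKT1", 20.0)])
        genetic = self.table([("AKT1", 12.0)])
        _, merged = consensus_hits(drug, genetic)
        out = tmp_path / "nodes.tsv"
        table = export_network_table(merged, out)
        assert len(table) == 1
        back = pd.read_csv(out, sep="\t")
        assert back.loc[0, "gene"] == "AKT1" and bool(back.loc[0, "consensus"])

    def test_empty_export_rejected(self):
        with pytest.raises(ConfigurationError):
            export_network_table(pd.DataFrame())
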