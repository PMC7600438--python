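import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cffvar.model import RiskSNP, ValidationError
from cffvar.simulate import gen_risk_snp_panel
from cffvar.snp_selection import filter_risk_snps, ld_r2, ld_r2_matrix, prune_ld


def snp(rsid, or_pub=1.2, chrom="1", **kwargs):
    defaults = dict(cancer_type="BC", risk_allele="A", maf=0.2, or_published=or_pub, chrom=chrom, pos=1)
    defaults.update(kwargs)
    return RiskSNP(rsid=rsid, **defaults)


class TestLdR2:
    def test_identical_vectors_give_one(self):
        a = np.array([0, 1, 2, 1, 0], dtype=float)
        assert ld_r2(a, a) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # cov = 3, var_a = var_b = 4 over n=6 -> r = 3/4, r^2 = 0.5625
        a = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        b = np.array([0, 1, 0, 1, 2, 2], dtype=float)
        assert ld_r2(a, b) == pytest.approx(0.5625)

    def test_zero_variance_undefined(self):
        assert math.isnan(ld_r2(np.zeros(5), np.array([0, 1, 2, 1, 0], dtype=float)))

    def test_missing_aware_co_observation(self):
        a = np.array([0, 1, 2, np.nan])
        b = np.array([0, 1, np.nan, 2])
        assert ld_r2(a, b) == pytest.approx(1.0)  # only first two co-called

    def test_independent_loci_null_expectation(self):
        # E[r^2] ~ 1/n for independent loci.
        rng = np.random.default_rng(3)
        n = 500
        values = [
            ld_r2(rng.binomial(2, 0.3, n).astype(float), rng.binomial(2, 0.3, n).astype(float))
            for _ in range(400)
        ]
        assert np.mean(values) == pytest.approx(1 / n, rel=0.35)


def brute_force_prune(snps, r2, threshold=0.8):
    """Independent oracle: components by boolean reachability (matrix powers),
    one survivor per component by max |ln OR| then smallest rsID."""
    ids = [s.rsid for s in snps]
    m = len(ids)
    adj = np.eye(m, dtype=bool)
    for i, j in itertools.combinations(range(m), 2):
        a, b = snps[i], snps[j]
        same_chrom = a.chrom is None or b.chrom is None or a.chrom == b.chrom
        try:
            value = float(r2.loc[a.rsid, b.rsid])
        except KeyError:
            continue
        if same_chrom and not np.isnan(value) and value > threshold:
            adj[i, j] = adj[j, i] = True
    reach = adj.copy()
    for _ in range(m):
        reach = reach | (reach @ adj)
    keep = set()
    seen = set()
    for i in range(m):
        if i in seen:
            continue
        component = [j for j in range(m) if reach[i, j]]
        seen.update(component)
        best = min(
            component,
            key=lambda j: (-abs(math.log(snps[j].or_published)) if snps[j].or_published else 0.0, ids[j]),
        )
        keep.add(ids[best])
    return [s for s in snps if s.rsid in keep]


def r2_frame(ids, pairs):
    df = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    np.fill_diagonal(df.values, 1.0)
    for (a, b), v in pairs.items():
        df.loc[a, b] = df.loc[b, a] = v
    return df


class TestPruneLd:
    def test_stronger_effect_survives(self):
        snps = [snp("rs1", 1.10), snp("rs2", 1.20)]
        r2 = r2_frame(["rs1", "rs2"], {("rs1", "rs2"): 0.9})
        assert [s.rsid for s in prune_ld(snps, r2)] == ["rs2"]

    def test_threshold_is_strict(self):
        snps = [snp("rs1", 1.10), snp("rs2", 1.20)]
        r2 = r2_frame(["rs1", "rs2"], {("rs1", "rs2"): 0.8})
        assert len(prune_ld(snps, r2)) == 2

    def test_tie_breaks_to_smallest_rsid(self):
        snps = [snp("rs9", 1.20), snp("rs10", 1.20)]
        r2 = r2_frame(["rs9", "rs10"], {("rs9", "rs10"): 0.95})
        assert [s.rsid for s in prune_ld(snps, r2)] == ["rs10"]

    def test_chain_matches_brute_force_oracle(self):
        # 5-SNP chain with alternating linked/unlinked pairs.
        ids = [f"rs{i}" for i in range(5)]
        snps = [snp(r, 1.05 + 0.03 * i) for i, r in enumerate(ids)]
        r2 = r2_frame(ids, {("rs0", "rs1"): 0.9, ("rs1", "rs2"): 0.5,
                            ("rs2", "rs3"): 0.95, ("rs3", "rs4"): 0.3})
        got = {s.rsid for s in prune_ld(snps, r2)}
        expected = {s.rsid for s in brute_force_prune(snps, r2)}
        assert got == expected

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            m = int(rng.integers(2, 9))
            ids = [f"rs{i}" for i in range(m)]
            snps = [snp(r, float(rng.uniform(1.04, 1.6))) for r in ids]
            pairs = {
                (ids[i], ids[j]): float(rng.uniform(0, 1))
                for i, j in itertools.combinations(range(m), 2)
            }
            r2 = r2_frame(ids, pairs)
            got = {s.rsid for s in prune_ld(snps, r2)}
            expected = {s.rsid for s in brute_force_prune(snps, r2)}
            assert got == expected

    def test_input_order_invariance(self):
        rng = np.random.default_rng(23)
        ids = [f"rs{i}" for i in range(6)]
        snps = [snp(r, float(rng.uniform(1.04, 1.6))) for r in ids]
        pairs = {
            (a, b): float(rng.uniform(0.5, 1.0)) for a, b in itertools.combinations(ids, 2)
        }
        r2 = r2_frame(ids, pairs)
        baseline = {s.rsid for s in prune_ld(snps, r2)}
        for perm_seed in range(5):
            perm = list(np.random.default_rng(perm_seed).permutation(len(snps)))
            assert {s.rsid for s in prune_ld([snps[i] for i in perm], r2)} == baseline


class TestFilterRiskSnps:
    def test_single_criterion_examples(self):
        retained, report = filter_risk_snps([snp("rs1", or_pub=1.03)])
        assert not retained and list(report["reason"]) == [3]
        retained, report = filter_risk_snps([snp("rs2", maf=0.50)])
        assert not retained and list(report["reason"]) == [2]
        retained, _ = filter_risk_snps([snp("rs3", maf=0.45)])  # boundary retained
        assert len(retained) == 1

    def test_six_snp_fixture_trips_each_criterion_once(self):
        ids = [f"rs{i}" for i in range(6)]
        snps = [
            snp(ids[0], risk_allele=None),
            snp(ids[1], maf=None),
            snp(ids[2], or_pub=1.02),
            snp(ids[3], subtype_specific=True),
            snp(ids[4], in_thousand_genomes=False),
            snp(ids[5], or_pub=1.30),
        ]
        # rs5 is linked to a phantom stronger partner rs6 to trigger criterion 6
        partner = snp("rs6", or_pub=1.50)
        snps.append(partner)
        r2 = r2_frame([s.rsid for s in snps], {(ids[5], "rs6"): 0.9})
        retained, report = filter_risk_snps(snps, r2=r2)
        assert [s.rsid for s in retained] == ["rs6"]
        assert sorted(report["reason"]) == [1, 2, 3, 4, 5, 6]

    def test_reasons_partition_input(self):
        snps, reference, truth = gen_risk_snp_panel(30, {1: 2, 2: 2, 3: 2, 4: 2, 5: 2, 6: 2}, seed=9)
        retained, report = filter_risk_snps(snps, reference)
        assert len(retained) + len(report) == len(snps)
        assert set(report["rsid"]).isdisjoint({s.rsid for s in retained})

    def test_planted_exclusions_recovered(self):
        snps, reference, truth = gen_risk_snp_panel(30, {1: 2, 2: 2, 3: 2, 4: 2, 5: 2, 6: 2}, seed=9)
        retained, report = filter_risk_snps(snps, reference)
        got = dict(zip(report["rsid"], report["reason"]))
        for rsid, reason in truth.items():
            if reason is None:
                assert rsid not in got
            else:
                assert got[rsid] == reason

    def test_idempotent_on_retained_list(self):
        snps, reference, _ = gen_risk_snp_panel(40, {2: 3, 6: 3}, seed=13)
        retained, _ = filter_risk_snps(snps, reference)
        again, report = filter_risk_snps(retained, reference)
        assert [s.rsid for s in again] == [s.rsid for s in retained]
        assert report.empty

    def test_duplicate_rsids_error(self):
        with pytest.raises(ValidationError):
            filter_risk_snps([snp("rs1"), snp("rs1")])


class TestGeneratorLd:
    def test_zero_flip_copy_has_r2_one(self):
        snps, reference, truth = gen_risk_snp_panel(5, {6: 1}, seed=2, flip_prob_linked=0.0)
        linked = next(r for r, reason in truth.items() if reason == 6)
        # find its partner: the clean SNP on the same chromosome
        linked_snp = next(s for s in snps if s.rsid == linked)
        partner = next(
            s
            for s in snps
            if truth[s.rsid] is None
            and s.chrom == linked_snp.chrom
            and s.pos == linked_snp.pos - 500
        )
        r2 = ld_r2(reference.column(linked), reference.column(partner.rsid))
        assert r2 == pytest.approx(1.0)
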