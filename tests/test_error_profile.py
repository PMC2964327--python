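"""Positional profiles, entropy statistics and mismatch-decay diagnostics."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from scipy import stats as sps

from v6prof.derep_cluster import ISU, OTU, cluster_otus, dereplicate
from v6prof.error_profile import (
    decay_curve,
    entropy_stats,
    flag_error_otus,
    primer_decay,
    primer_profile,
    profile_positions,
)
from v6prof.simulate import CommunityProfile, SimConfig
from tests.conftest import run_chain


def _rand_seq(seed: int, n: int = 76) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _single_otu(isus):
    return OTU(
        otu_id=0,
        seed_isu_id=0,
        members=[(i.isu_id, 0 if i.isu_id == 0 else 1, 1.0) for i in isus],
        total_count=sum(i.total_count for i in isus),
        per_sample_counts={},
    )


# ---------------------------------------------------------------------------
# positional profiles


def test_single_isu_profile_is_unanimous():
    seed = _rand_seq(1)
    otu = _single_otu([ISU(0, seed, 42, {"s": 42})])
    prof = profile_positions(otu, [ISU(0, seed, 42, {"s": 42})])
    assert prof.consensus == seed
    assert (prof.counts.sum(axis=0) == 42).all()
    assert (prof.counts.max(axis=0) == 42).all()


def test_two_isu_profile_splits_one_column():
    seed = _rand_seq(2)
    pos = 30
    variant = seed[:pos] + ("A" if seed[pos] != "A" else "G") + seed[pos + 1:]
    isus = [ISU(0, seed, 60, {"s": 60}), ISU(1, variant, 40, {"s": 40})]
    prof = profile_positions(_single_otu(isus), isus)
    freqs = prof.frequencies
    for j in range(len(seed)):
        if j == pos:
            assert sorted(prof.counts[:, j][prof.counts[:, j] > 0]) == [40, 60]
        else:
            assert freqs[:, j].max() == 1.0
    assert prof.consensus == seed


def test_deleted_position_contributes_nothing():
    seed = _rand_seq(3)
    shorter = seed[:40] + seed[41:]  # one deletion
    isus = [ISU(0, seed, 10, {"s": 10}), ISU(1, shorter, 5, {"s": 5})]
    prof = profile_positions(_single_otu(isus), isus)
    coverage = prof.counts.sum(axis=0)
    # exactly one column is covered by the seed alone (the gap may sit at
    # any equivalent position inside a repeat)
    assert (coverage == 10).sum() == 1
    assert (coverage == 15).sum() == 75
    assert prof.counts.sum() == 15 * 76 - 5


def test_empty_otu_errors():
    otu = OTU(otu_id=0, seed_isu_id=0, members=[], total_count=0, per_sample_counts={})
    with pytest.raises(ValueError):
        profile_positions(otu, [])


# ---------------------------------------------------------------------------
# entropy statistics


def test_unanimous_profile_is_homogeneous():
    seed = _rand_seq(4)
    isus = [ISU(0, seed, 42, {"s": 42})]
    est = entropy_stats(profile_positions(_single_otu(isus), isus))
    assert (est.h == 0).all()
    assert est.skew == est.sigma == est.q == 0.0
    assert est.classification == "homogeneous"


def test_single_5050_column_closed_form():
    """One 50/50 column among 75 unanimous: h_max = 1 bit, sigma and skew
    follow directly from a one-hot entropy vector."""
    seed = _rand_seq(5)
    variant = seed[:10] + ("C" if seed[10] != "C" else "T") + seed[11:]
    isus = [ISU(0, seed, 50, {"s": 50}), ISU(1, variant, 50, {"s": 50})]
    est = entropy_stats(profile_positions(_single_otu(isus), isus))
    L, p = 76, 1 / 76
    sd = math.sqrt(p * (1 - p))  # population sd of one 1 among 75 zeros
    assert est.max == pytest.approx(1.0)
    assert est.mean == pytest.approx(p)
    assert est.sigma == pytest.approx((1 - p) / sd)
    expected_skew = (1 - 2 * p) / math.sqrt(p * (1 - p))
    assert est.skew == pytest.approx(expected_skew)
    assert est.q == 0.0  # p95 equals the median for a single spike
    assert est.classification == "mixed"


def test_6040_mixture_at_three_positions():
    seed = _rand_seq(6)
    chars = list(seed)
    for i in (10, 30, 50):
        chars[i] = "A" if seed[i] != "A" else "G"
    isus = [ISU(0, seed, 60, {"s": 60}), ISU(1, "".join(chars), 40, {"s": 40})]
    est = entropy_stats(profile_positions(_single_otu(isus), isus))
    h_mix = -(0.6 * math.log2(0.6) + 0.4 * math.log2(0.4))
    assert h_mix == pytest.approx(0.971, abs=1e-3)
    for i in (10, 30, 50):
        assert est.h[i] == pytest.approx(h_mix)
    assert est.classification == "mixed"


def test_entropy_bounds(noisy_chain):
    for otu in noisy_chain.otus[:10]:
        est = entropy_stats(profile_positions(otu, noisy_chain.isus))
        assert (est.h >= 0).all() and (est.h <= 2.0 + 1e-12).all()


def test_uniform_column_reaches_two_bits():
    isus = [
        ISU(0, "AAAA", 1, {"s": 1}),
        ISU(1, "CAAA", 1, {"s": 1}),
        ISU(2, "GAAA", 1, {"s": 1}),
        ISU(3, "TAAA", 1, {"s": 1}),
    ]
    otu = OTU(0, 0, [(0, 0, 1.0), (1, 1, 0.75), (2, 1, 0.75), (3, 1, 0.75)], 4, {})
    est = entropy_stats(profile_positions(otu, isus))
    assert est.h[0] == pytest.approx(2.0)


def test_all_zero_profile_errors():
    from v6prof.error_profile import PositionProfile

    prof = PositionProfile(feature_id="x", counts=np.zeros((4, 10)), consensus="A" * 10)
    with pytest.raises(ValueError):
        entropy_stats(prof)


# ---------------------------------------------------------------------------
# primer profiles


def test_noise_free_primer_profile_clean_except_degenerate_position(
    clean_chain, primers
):
    lprof, rprof = primer_profile(clean_chain.records, primers)
    r_pos = primers.left.find("R")
    n = len(clean_chain.records)
    for j, letter in enumerate(primers.left):
        col = lprof.counts[:, j]
        assert col.sum() == n
        if j == r_pos:
            a, g = col[0], col[2]  # rows A and G
            assert a + g == n and a > 0 and g > 0
        else:
            assert col.max() == n  # unanimous
    for j in range(len(primers.right)):
        assert rprof.counts[:, j].max() == n


def test_pcr_error_rate_flat_across_primer_positions(fixture6, tags, primers):
    """With position-independent PCR error the off-consensus frequency has
    no trend along the primer."""
    communities, sheet = fixture6
    single = {s: CommunityProfile([(communities["sample1"].sequences[0], 1.0)])
              for s in sheet.sample_ids}
    cfg = SimConfig(n_reads=4000, pcr_error_rate=4e-4, sequencing_errors=False,
                    chimera_rate=0.0, seed=31)
    chain = run_chain({k: single[k] for k in sheet.sample_ids}, sheet, tags, primers, cfg)
    lprof, rprof = primer_profile(chain.records, primers)
    r_pos = primers.left.find("R")
    xs, ys = [], []
    for prof, plen, skip in ((lprof, 19, {r_pos}), (rprof, 18, set())):
        for j in range(plen):
            if j in skip:
                continue
            col = prof.counts[:, j]
            xs.append(len(xs))
            ys.append(1 - col.max() / col.sum())
    res = sps.linregress(xs, ys)
    assert abs(res.slope) < 5e-5
    assert res.pvalue > 0.01


# ---------------------------------------------------------------------------
# decay curves


def test_single_isu_otu_decay_mass_at_zero():
    seed = _rand_seq(7)
    isus = [ISU(0, seed, 10, {"s": 10})]
    otu = OTU(0, 0, [(0, 0, 1.0)], 10, {})
    curve = decay_curve(otu, isus)
    assert curve.fractions.tolist() == [1.0]


def test_decay_curve_normalizes(noisy_chain):
    for otu in noisy_chain.otus[:10]:
        assert decay_curve(otu, noisy_chain.isus).fractions.sum() == pytest.approx(1.0)


def test_pcr_errors_give_monotone_decay(fixture6, tags, primers):
    communities, sheet = fixture6
    single = {s: CommunityProfile([(communities["sample1"].sequences[0], 1.0)])
              for s in sheet.sample_ids}
    cfg = SimConfig(n_reads=3000, pcr_error_rate=2e-4, sequencing_errors=False,
                    seed=43)
    chain = run_chain(single, sheet, tags, primers, cfg)
    assert len(chain.otus) >= 1
    curve = decay_curve(chain.otus[0], chain.isus)
    assert (np.diff(curve.fractions) <= 0).all()


def test_two_template_mixture_breaks_decay(tags, primers, fixture6):
    """Two templates 4 edits apart at comparable abundance: a mass spike at
    k=4 interrupts the monotone error decay."""
    _, sheet = fixture6
    base = _rand_seq(10, n=80)  # at 80 nt, 4 edits is exactly 95% identity
    chars = list(base)
    for i in (12, 25, 44, 60):
        chars[i] = "A" if base[i] != "A" else "T"
    mix = CommunityProfile([(base, 0.7), ("".join(chars), 0.3)])
    cfg = SimConfig(n_reads=2000, pcr_error_rate=5e-5, sequencing_errors=True,
                    seed=17)
    chain = run_chain({s: mix for s in sheet.sample_ids}, sheet, tags, primers, cfg)
    otu = chain.otus[0]
    # the minor template sits in the main OTU at distance 4
    assert any(d == 4 for _, d, _ in otu.members)
    curve = decay_curve(otu, chain.isus)
    assert curve.fractions[4] > curve.fractions[3]
    assert curve.fractions[4] > curve.fractions[2]


def test_primer_decay_monotone_on_simulation(noisy_chain, primers):
    curve = primer_decay(noisy_chain.records, primers)
    assert curve.fractions.sum() == pytest.approx(1.0)
    assert curve.fractions[0] > 0.8
    assert (np.diff(curve.fractions) <= 0).all()


# ---------------------------------------------------------------------------
# PCR-ghost OTUs


def test_ghost_flagging_threshold():
    seed = _rand_seq(11)
    far = _rand_seq(12)
    mk = lambda i, seq, n: ISU(i, seq, n, {"s": n})
    # seed 1000 vs 50 far reads: not flagged
    isus = [mk(0, seed, 1000), mk(1, far, 50)]
    otus = [OTU(0, 0, [(0, 0, 1.0), (1, 2, 0.97)], 1050, {})]
    assert flag_error_otus(otus, isus) == []
    # seed 3 vs 900 at distance 2-3: flagged (300x >= 100x)
    isus = [mk(0, seed, 3), mk(1, far, 500), mk(2, _rand_seq(13), 400)]
    otus = [OTU(0, 0, [(0, 0, 1.0), (1, 2, 0.97), (2, 3, 0.96)], 903, {})]
    assert flag_error_otus(otus, isus) == [0]


def test_ghost_otu_detected_in_error_cloud_split():
    """An abundant template's error cloud split across the identity
    threshold: the far shard becomes an OTU whose seed is outnumbered by
    distance>=2 members."""
    rng = random.Random(20)
    template = _rand_seq(21)

    def mutate(seq, positions):
        chars = list(seq)
        for i in positions:
            chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
        return "".join(chars)

    reads = [("s", template)] * 5000
    # near cloud (distance 1 from template) stays in the main OTU
    for k in range(40):
        reads += [("s", mutate(template, rng.sample(range(76), 1)))] * 12
    # shard: a distance-4 variant with a halo of many distinct low-count
    # distance-2 descendants (the hallmark: the halo total dwarfs the seed)
    shard_positions = {3, 20, 40, 66}
    shard_seed = mutate(template, sorted(shard_positions))
    reads += [("s", shard_seed)] * 8
    from itertools import combinations

    halo_pairs = [
        pair for pair in combinations(range(76), 2)
        if not shard_positions & set(pair)
    ][:250]
    for k, pair in enumerate(halo_pairs):
        reads += [("s", mutate(shard_seed, pair))] * (1 + k % 7)
    isus, _ = dereplicate(reads)
    otus = cluster_otus(isus, 0.95)
    ghosts = flag_error_otus(otus, isus, ratio_cutoff=100.0)
    shard_otus = [o for o in otus if isus[o.seed_isu_id].seq == shard_seed]
    assert shard_otus and shard_otus[0].otu_id in ghosts
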