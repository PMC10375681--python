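import numpy as np
import pytest

from conftest import make_records
from mitorea.calling import (
    CallParams,
    DegenerateInputError,
    call_position,
    call_subject,
    fit_genotype,
    minor_allele_fraction,
    write_snp_view,
    write_vcf,
)
from mitorea.synthetic import SimConfig, simulate_position, simulate_cohort

HI, LO = 1000.0, 50.0


def _mix(f, major="A", minor="G"):
    """Noise-free channel vector for a major/minor mixture."""
    vals = {b: LO for b in "ACGT"}
    vals[major] = LO + (HI - LO) * (1 - f)
    vals[minor] = LO + (HI - LO) * f
    return [vals[b] for b in "ACGT"]


def test_pure_base_pattern_fits_single_model():
    sense, anti = make_records([HI, LO, LO, LO], [HI, LO, LO, LO])
    fit = fit_genotype(sense, anti)
    assert fit.best_model == ("A",)
    assert fit.quality > 3


def test_balanced_mixture_fits_pair_model():
    sense, anti = make_records(_mix(0.5), _mix(0.5))
    fit = fit_genotype(sense, anti)
    assert fit.best_model == ("A", "G")
    assert fit.rss[("A", "G")] == pytest.approx(0.0, abs=1e-12)


def test_flat_intensities_give_zero_quality_and_no_call():
    sense, anti = make_records([100] * 4, [100] * 4)
    fit = fit_genotype(sense, anti)
    assert fit.quality == pytest.approx(0.0, abs=1e-12)
    call = call_position(fit, ref_base="A")
    assert call.state == "no-call"


def test_all_zero_intensities_rejected():
    sense, anti = make_records([0] * 4, [0] * 4)
    with pytest.raises(DegenerateInputError):
        fit_genotype(sense, anti)


@pytest.mark.parametrize("f", [0.3, 0.5])
def test_minor_fraction_exact_on_noise_free_input(f):
    sense, anti = make_records(_mix(f), _mix(f))
    assert minor_allele_fraction(sense, anti, ("A", "G")) == pytest.approx(f)


def test_minor_fraction_noise_robust_mean():
    """Planted f=0.35 under multiplicative lognormal noise: mean estimate
    over 200 positions stays within +/-0.03."""
    config = SimConfig(sigma=0.1)
    rng = np.random.default_rng(123)
    est = []
    for _ in range(200):
        sense, anti = simulate_position(("A", "G"), 0.35, config, rng)
        est.append(minor_allele_fraction(sense, anti, ("A", "G")))
    assert abs(np.mean(est) - 0.35) < 0.03


def test_minor_fraction_degenerate_denominator():
    sense, anti = make_records([100, 100, 10, 10], [100, 100, 10, 10])
    with pytest.raises(DegenerateInputError):
        minor_allele_fraction(sense, anti, ("G", "T"))


def test_call_position_state_logic():
    # homozygous reference
    sense, anti = make_records([HI, LO, LO, LO], [HI, LO, LO, LO])
    assert call_position(fit_genotype(sense, anti), "A").state == "reference"
    # homozygous non-reference
    assert call_position(fit_genotype(sense, anti), "C").state == "homoplasmic"
    # mid-range heteroplasmy
    sense, anti = make_records(_mix(0.35), _mix(0.35))
    call = call_position(fit_genotype(sense, anti), "A")
    assert call.state == "heteroplasmic"
    assert call.called_alleles == ("A", "G")
    assert call.minor_fraction == pytest.approx(0.35)
    # low-level regime collapses to the major allele
    sense, anti = make_records(_mix(0.10), _mix(0.10))
    call = call_position(fit_genotype(sense, anti), "A")
    assert call.state == "reference"
    assert call.minor_fraction is None


def test_detection_starts_exactly_at_range_lower_bound():
    """Sweeping the planted minor fraction upward in 5% steps on noise-free
    input, the first heteroplasmic call appears exactly at 20%."""
    config = SimConfig(sigma=0.0)
    rng = np.random.default_rng(0)
    states = {}
    for pct in range(5, 55, 5):
        sense, anti = simulate_position(("A", "G"), pct / 100, config, rng)
        states[pct] = call_position(fit_genotype(sense, anti), "A").state
    het = [p for p, s in states.items() if s == "heteroplasmic"]
    assert min(het) == 20
    assert het == list(range(20, 55, 5))


def test_call_subject_recovers_planted_truth_exactly(genome):
    """High-SNR cohort: per-subject homoplasmic and heteroplasmic counts
    equal the truth ledger (sensitivity 1, no false positives)."""
    config = SimConfig(groups={"CTRL": 2, "maternal": 2}, structure_seed=7,
                       noise_seed=8)
    cohort = simulate_cohort(config, genome)
    for truth in cohort.truth.subjects:
        cs = call_subject(cohort.intensities[truth.subject_id], genome)
        assert cs.n_homoplasmic == truth.count("homoplasmic")
        assert cs.n_heteroplasmic == truth.count("heteroplasmic")
        assert cs.recount() == (cs.n_homoplasmic, cs.n_heteroplasmic)
        called_hom = {c.position for c in cs.variants("homoplasmic")}
        truth_hom = {v.position for v in truth.variants
                     if v.mutation_class == "homoplasmic"}
        assert called_hom == truth_hom


def test_zero_variant_subject_calls_clean(genome):
    """All rates zero, no noise: every position pure reference, no calls."""
    config = SimConfig(groups={"CTRL": 1}, hom_rate_per_kb=0.0,
                       het_rate_per_kb=0.0, lowlevel_rate=0.0, sigma=0.0,
                       haplogroup_probs={"rCRS": 1.0})
    cohort = simulate_cohort(config, genome)
    assert cohort.truth.subjects[0].variants == []
    cs = call_subject(next(iter(cohort.intensities.values())), genome)
    assert cs.n_homoplasmic == 0
    assert cs.n_heteroplasmic == 0
    assert int((cs.states == 3).sum()) == 0


def test_calling_is_deterministic(genome, small_cohort):
    sub = next(iter(small_cohort.intensities.values()))
    assert call_subject(sub, genome) == call_subject(sub, genome)


def test_strand_symmetry(genome, small_cohort):
    """Swapping sense and antisense records (already complement re-indexed)
    leaves every call unchanged."""
    from mitorea.arraydata import SubjectIntensities

    sub = next(iter(small_cohort.intensities.values()))
    swapped = SubjectIntensities(
        sub.subject_id, sub.sample_type, sub.positions, sub.values[:, ::-1, :]
    )
    a = call_subject(sub, genome)
    b = call_subject(swapped, genome)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.allele1, b.allele1)
    assert np.array_equal(a.allele2, b.allele2)
    assert np.allclose(a.minor_fraction, b.minor_fraction, equal_nan=True)
    assert np.allclose(a.quality, b.quality)


def test_raising_quality_threshold_never_decreases_no_calls(genome, small_cohort):
    sub = next(iter(small_cohort.intensities.values()))
    prev = -1
    for threshold in (1.0, 3.0, 9.0, 50.0, 200.0):
        cs = call_subject(sub, genome, CallParams(quality_threshold=threshold))
        n_nc = int((cs.states == 3).sum())
        assert n_nc >= prev
        prev = n_nc


def test_exports_write_parseable_files(tmp_path, genome, small_cohort):
    sub = next(iter(small_cohort.intensities.values()))
    cs = call_subject(sub, genome)
    write_snp_view(cs, tmp_path / "snp.tsv")
    write_vcf(cs, genome, tmp_path / "calls.vcf")
    import pandas as pd

    snp = pd.read_csv(tmp_path / "snp.tsv", sep="\t")
    assert len(snp) == 16_544
    assert set(snp["state"]) <= {"reference", "homoplasmic", "heteroplasmic",
                                 "no-call"}
    vcf_lines = [l for l in (tmp_path / "calls.vcf").read_text().splitlines()
                 if not l.startswith("#")]
    assert len(vcf_lines) == cs.n_homoplasmic + cs.n_heteroplasmic
    assert all(l.split("\t")[0] == "chrM" for l in vcf_lines)
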