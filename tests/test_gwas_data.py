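"""Summary-statistic I/O, instrument selection and allele harmonisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrphewas.gwas_data import (
    SummaryStatsFormatError,
    HarmonisationError,
    VariantAssociation,
    harmonise_pair,
    outcome_record,
    read_summary_stats,
    select_instruments,
    write_summary_stats,
)

from conftest import make_assoc


# ---------------------------------------------------------------------------
# I/O


def _random_assocs(seed: int, n: int) -> list[VariantAssociation]:
    rng = np.random.default_rng(seed)
    pairs = [("A", "G"), ("T", "C"), ("A", "T"), ("C", "G")]
    out = []
    for i in range(n):
        ea, oa = pairs[rng.integers(len(pairs))]
        out.append(
            make_assoc(
                variant_id=f"rs{i}",
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 10**8)),
                effect_allele=ea,
                other_allele=oa,
                eaf=None if rng.random() < 0.1 else float(rng.uniform(0.01, 0.99)),
                beta=float(rng.normal(0, 0.2)),
                se=float(rng.uniform(0.01, 0.1)),
                pval=float(rng.uniform(1e-12, 1)),
                n=None if rng.random() < 0.1 else float(rng.integers(1000, 500000)),
            )
        )
    return out


def test_round_trip_preserves_all_fields(tmp_path):
    assocs = _random_assocs(seed=7, n=50)
    path = tmp_path / "stats.tsv"
    write_summary_stats(assocs, path)
    back = read_summary_stats(path)
    assert back == assocs


def test_read_preserves_row_order_and_skips_invalid(tmp_path, caplog):
    path = tmp_path / "stats.tsv"
    path.write_text(
        "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
        "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.05\t0.01\t1000\n"
        "rs2\t1\t200\tAT\tG\t0.2\t0.1\t0.05\t0.01\t1000\n"  # indel: skipped
        "rs3\t2\t300\tc\tt\t0.4\t-0.2\t0.04\t0.001\t1000\n"  # lowercase ok
        "rs4\t2\t400\tA\tG\t0.2\t0.1\t0\t0.01\t1000\n"  # se = 0: skipped
    )
    recs = read_summary_stats(path)
    assert [r.variant_id for r in recs] == ["rs1", "rs3"]
    assert recs[1].effect_allele == "C" and recs[1].other_allele == "T"


def test_read_accepts_common_aliases(tmp_path):
    path = tmp_path / "stats.tsv"
    path.write_text(
        "SNP\tchr\tbp\tA1\tA2\tfreq\tb\tse\tp\tN\n"
        "rs1\t3\t500\ta\tg\t0.25\t0.12\t0.03\t1e-5\t5000\n"
    )
    (rec,) = read_summary_stats(path)
    assert rec.variant_id == "rs1" and rec.chrom == "3" and rec.eaf == 0.25


def test_read_missing_column_names_it(tmp_path):
    path = tmp_path / "stats.tsv"
    path.write_text("variant_id\tchrom\tpos\n" "rs1\t1\t100\n")
    with pytest.raises(SummaryStatsFormatError, match="effect_allele"):
        read_summary_stats(path)


def test_read_empty_file_errors(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with pytest.raises(SummaryStatsFormatError):
        read_summary_stats(path)


def test_write_empty_list_gives_header_only(tmp_path):
    path = tmp_path / "out.tsv"
    write_summary_stats([], path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("variant_id\t")
    write_summary_stats([make_assoc()], path)
    assert len(path.read_text().splitlines()) == 2


# ---------------------------------------------------------------------------
# Instrument selection


def test_select_instruments_strict_inequality():
    assocs = [
        make_assoc("rs_a", pval=1e-9),
        make_assoc("rs_b", pval=1e-7),
        make_assoc("rs_c", pval=1e-8),
    ]
    sel = select_instruments(assocs, 5e-8)
    assert [a.variant_id for a in sel] == ["rs_a", "rs_c"]
    assert select_instruments([make_assoc(pval=0.5)] * 3, 5e-8) == []


@given(
    pvals=st.lists(st.floats(min_value=1e-300, max_value=1.0), min_size=0, max_size=30),
    threshold=st.floats(min_value=1e-10, max_value=0.99),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_select_instruments_equals_bruteforce(pvals, threshold):
    assocs = [make_assoc(f"rs{i}", pval=p) for i, p in enumerate(pvals)]
    got = select_instruments(assocs, threshold)
    expected = sorted(
        (a for a in assocs if a.pval < threshold), key=lambda a: (a.pval, a.variant_id)
    )
    assert got == expected


def test_simulator_instruments_all_reach_significance():
    from mrphewas.synthetic_data import SimulationConfig, simulate_two_sample

    ds = simulate_two_sample(SimulationConfig(seed=11))
    sel = select_instruments(ds.exposure)
    causal = set(ds.truth["causal_variant_ids"])
    assert len([a for a in sel if a.variant_id in causal]) >= 25
    brute = [a for a in ds.exposure if a.pval < 5e-8]
    assert {a.variant_id for a in sel} == {a.variant_id for a in brute}


# ---------------------------------------------------------------------------
# Harmonisation


def test_harmonise_swapped_alleles_flip():
    exp = make_assoc(effect_allele="A", other_allele="G", beta=0.10)
    out = make_assoc(effect_allele="G", other_allele="A", beta=0.05, eaf=0.3)
    h = harmonise_pair(exp, out)
    assert h.action == "flipped"
    assert h.outcome_beta == -0.05
    assert h.outcome_eaf == pytest.approx(0.7)


def test_harmonise_strand_complement():
    exp = make_assoc(effect_allele="A", other_allele="G", beta=0.10)
    # same variant reported on the opposite strand, same order
    out = make_assoc(effect_allele="T", other_allele="C", beta=0.05)
    h = harmonise_pair(exp, out)
    assert h.action == "kept" and h.outcome_beta == 0.05
    # opposite strand AND swapped order
    out2 = make_assoc(effect_allele="C", other_allele="T", beta=0.05, eaf=0.3)
    h2 = harmonise_pair(exp, out2)
    assert h2.action == "flipped" and h2.outcome_beta == -0.05


def test_harmonise_palindrome_opposite_frequencies_flip():
    exp = make_assoc(effect_allele="A", other_allele="T", beta=0.2, eaf=0.10)
    out = make_assoc(effect_allele="A", other_allele="T", beta=0.1, eaf=0.88)
    h = harmonise_pair(exp, out)
    assert h.action == "flipped"
    assert h.outcome_beta == pytest.approx(-0.1)
    assert h.outcome_eaf == pytest.approx(0.12)


def test_harmonise_palindrome_concordant_frequencies_kept():
    exp = make_assoc(effect_allele="C", other_allele="G", beta=0.2, eaf=0.10)
    out = make_assoc(effect_allele="C", other_allele="G", beta=0.1, eaf=0.15)
    h = harmonise_pair(exp, out)
    assert h.action == "palindromic_resolved" and h.outcome_beta == 0.1


@pytest.mark.parametrize(
    "exp_eaf,out_eaf",
    [(0.50, 0.2), (0.2, 0.50), (0.42, 0.2), (0.58, 0.2), (None, 0.2), (0.2, None)],
)
def test_harmonise_palindrome_ambiguous_dropped(exp_eaf, out_eaf):
    exp = make_assoc(effect_allele="C", other_allele="G", eaf=exp_eaf)
    out = make_assoc(effect_allele="C", other_allele="G", eaf=out_eaf)
    h = harmonise_pair(exp, out)
    assert h.action == "dropped" and h.drop_reason == "ambiguous_palindrome"
    assert not h.usable


def test_harmonise_incompatible_alleles_dropped():
    exp = make_assoc(effect_allele="A", other_allele="G")
    out = make_assoc(effect_allele="A", other_allele="C")
    h = harmonise_pair(exp, out)
    assert h.action == "dropped" and h.drop_reason == "allele_mismatch"


def test_harmonise_mismatched_ids_require_proxy_declaration():
    exp = make_assoc("rs1")
    out = make_assoc("rs2")
    with pytest.raises(HarmonisationError):
        harmonise_pair(exp, out)
    h = harmonise_pair(exp, out, proxy_of="rs2")
    assert h.usable and h.proxy_of == "rs2"


_allele_pairs = st.sampled_from(
    [("A", "G"), ("G", "A"), ("T", "C"), ("C", "T"), ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
)


@given(
    pair=_allele_pairs,
    swap=st.booleans(),
    complement=st.booleans(),
    exp_eaf=st.floats(min_value=0.01, max_value=0.99),
    out_eaf=st.floats(min_value=0.01, max_value=0.99),
    beta=st.floats(min_value=-1, max_value=1),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_harmonise_idempotent(pair, swap, complement, exp_eaf, out_eaf, beta):
    """Re-harmonising a kept/flipped output changes nothing."""
    from mrphewas.gwas_data import COMPLEMENT

    ea, oa = pair
    exp = make_assoc(effect_allele=ea, other_allele=oa, eaf=exp_eaf, beta=0.2)
    oea, ooa = (oa, ea) if swap else (ea, oa)
    if complement:
        oea, ooa = COMPLEMENT[oea], COMPLEMENT[ooa]
    out = make_assoc(effect_allele=oea, other_allele=ooa, eaf=out_eaf, beta=beta)
    h1 = harmonise_pair(exp, out)
    if not h1.usable:
        return
    h2 = harmonise_pair(exp, outcome_record(h1))
    assert h2.outcome_beta == pytest.approx(h1.outcome_beta, abs=1e-12)
    assert (h2.outcome_eaf or 0) == pytest.approx(h1.outcome_eaf or 0, abs=1e-12)
    assert h2.action in ("kept", "palindromic_resolved")


@given(
    exp_eaf=st.floats(min_value=0.01, max_value=0.99),
    out_eaf=st.floats(min_value=0.01, max_value=0.99),
    beta=st.floats(min_value=-1, max_value=1),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_flip_involution(exp_eaf, out_eaf, beta):
    """Swapping outcome alleles and negating its beta leaves estimation unchanged."""
    exp = make_assoc(effect_allele="A", other_allele="G", eaf=exp_eaf)
    out = make_assoc(effect_allele="A", other_allele="G", eaf=out_eaf, beta=beta)
    flipped_out = make_assoc(
        effect_allele="G", other_allele="A", eaf=1 - out_eaf, beta=-beta
    )
    h = harmonise_pair(exp, out)
    h_flipped = harmonise_pair(exp, flipped_out)
    assert h_flipped.outcome_beta == pytest.approx(h.outcome_beta, abs=1e-12)
    assert h_flipped.outcome_se == h.outcome_se
    assert h_flipped.effect_allele == h.effect_allele
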