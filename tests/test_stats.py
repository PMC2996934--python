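"""Resource statistics: categories, spacing, windows, informativeness, N50."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from felsnp import published
from felsnp.io import ReferenceAssembly
from felsnp.nqs import VariantSite
from felsnp.stats import (
    bases_per_snp,
    categorize,
    estimate_homozygous_fraction,
    informative_fraction,
    n50,
    occupancy_curve,
    window_density,
)

from oracles import oracle_bin_counts, oracle_n50, oracle_partition


def site(chrom, pos, discoverers, alt="G"):
    return VariantSite(
        chrom=chrom,
        pos=pos,
        vtype="SNP",
        ref="A",
        alt=alt,
        support={d: 1 for d in discoverers},
    )


CATS = ["Pixel", "Zeelie", "Tipper", "Scooter", "Speedy", "Cocoa", "Nancy", "Cinnamon"]


class TestCategorize:
    @pytest.mark.parametrize(
        "discoverers,in_a,in_b",
        [
            ({"Nancy"}, False, True),            # wildcat only: B and C
            ({"Cinnamon"}, False, False),        # inbred only: C only
            ({"Pixel", "Nancy"}, True, True),    # a breed cat too: A, B, C
            ({"Cinnamon", "Nancy"}, False, True),
            ({"Cocoa"}, True, True),
        ],
    )
    def test_membership_rules(self, discoverers, in_a, in_b):
        part = categorize([site("chr1", 5, discoverers)])
        assert bool(part.in_a[0]) is in_a
        assert bool(part.in_b[0]) is in_b
        assert len(part.sites_in("C")) == 1

    def test_unknown_special_name_rejected(self):
        with pytest.raises(ValueError, match="unknown individual"):
            categorize(
                [site("chr1", 5, {"Pixel"})],
                special={"Cinnamon", "Garfield"},
                known_individuals=CATS,
            )

    def test_nesting_and_counts_match_brute_force(self):
        rng = np.random.default_rng(17)
        sites = []
        for i in range(300):
            k = int(rng.integers(1, 4))
            disc = set(rng.choice(CATS, size=k, replace=False))
            sites.append(site("chr1", i * 10, disc))
        part = categorize(sites)
        want = oracle_partition(
            [s.discoverers for s in sites], {"Cinnamon", "Nancy"}, {"Cinnamon"}
        )
        assert [(bool(a), bool(b)) for a, b in zip(part.in_a, part.in_b)] == want
        a, b, c = (
            {s.key for s in part.sites_in(cat)} for cat in "ABC"
        )
        assert a <= b <= c
        counts = part.counts()
        assert counts["A"] <= counts["B"] <= counts["C"]
        by_chrom = part.counts_by_chrom()
        assert by_chrom["A"].sum() == counts["A"]


class TestBasesPerSnp:
    def test_reproduces_every_published_cell(self):
        rows = list(published.PER_CHROMOSOME) + [published.GENOME_TOTAL]
        for chrom, non_n, a, b, c, bps_a, bps_b, bps_c in rows:
            assert bases_per_snp(non_n, a) == bps_a, chrom
            assert bases_per_snp(non_n, b) == bps_b, chrom
            assert bases_per_snp(non_n, c) == bps_c, chrom

    def test_zero_snps_is_undefined(self):
        assert bases_per_snp(123_456, 0) is None

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bases_per_snp(-1, 5)


class TestWindows:
    def test_two_windows_one_snp_each(self):
        asm = ReferenceAssembly({"chr1": "ACGT" * 500_000})  # 2 Mb
        sites = [site("chr1", 500_000, {"Pixel"}), site("chr1", 1_500_000, {"Pixel"})]
        wt = window_density(sites, asm, window=1_000_000)
        assert wt.table["count"].tolist() == [1, 1]
        assert wt.table["determined"].all()

    def test_all_n_chromosome_fully_undetermined(self):
        asm = ReferenceAssembly({"chr1": "N" * 2_500_000})
        wt = window_density([], asm, window=1_000_000)
        assert not wt.table["determined"].any()
        assert len(wt.table) == 3  # final partial window kept

    def test_counts_match_binning_oracle(self):
        length = 777_000
        asm = ReferenceAssembly({"chr1": "A" * length})
        rng = np.random.default_rng(23)
        pos = rng.integers(0, length, size=500)
        sites = [site("chr1", int(p), {"Pixel"}) for p in pos]
        wt = window_density(sites, asm, window=50_000)
        assert wt.table["count"].tolist() == oracle_bin_counts(pos, length, 50_000)
        assert wt.table["count"].sum() == 500

    def test_window_must_be_positive(self):
        asm = ReferenceAssembly({"chr1": "ACGT"})
        with pytest.raises(ValueError):
            window_density([], asm, window=0)


class TestOccupancy:
    def test_single_giant_window(self):
        asm = ReferenceAssembly({"chr1": "ACGT" * 1_000})
        curve = occupancy_curve([site("chr1", 7, {"Pixel"})], asm, [10_000])
        assert curve.fraction.tolist() == [1.0]

    def test_no_snps_zero_everywhere(self):
        asm = ReferenceAssembly({"chr1": "ACGT" * 1_000})
        curve = occupancy_curve([], asm, [100, 1_000])
        assert curve.fraction.tolist() == [0.0, 0.0]

    def test_matches_binning_oracle_and_monotone_on_nested_sizes(self):
        length = 64_000
        asm = ReferenceAssembly({"chr1": "A" * length})
        rng = np.random.default_rng(29)
        pos = sorted(set(int(p) for p in rng.integers(0, length, size=120)))
        sites = [site("chr1", p, {"Pixel"}) for p in pos]
        sizes = [1_000, 2_000, 4_000, 8_000]
        curve = occupancy_curve(sites, asm, sizes)
        for row, size in zip(curve.itertuples(), sizes):
            counts = oracle_bin_counts(pos, length, size)
            assert row.occupied_windows == sum(c > 0 for c in counts)
            assert row.determined_windows == len(counts)
        fr = curve.fraction.tolist()
        assert fr == sorted(fr)  # nested tilings: non-decreasing

    def test_size_one_on_fully_mapped_assembly_is_site_density(self):
        length = 5_000
        asm = ReferenceAssembly({"chr1": "C" * length})
        pos = [10, 20, 30, 4_000]
        sites = [site("chr1", p, {"Pixel"}) for p in pos]
        curve = occupancy_curve(sites, asm, [1])
        assert curve.fraction.tolist() == [len(pos) / length]

    def test_empty_size_list_rejected(self):
        asm = ReferenceAssembly({"chr1": "ACGT"})
        with pytest.raises(ValueError):
            occupancy_curve([], asm, [])

    def test_undetermined_windows_excluded_unless_requested(self):
        asm = ReferenceAssembly({"chr1": "A" * 1_000 + "N" * 1_000})
        sites = [site("chr1", 500, {"Pixel"})]
        strict = occupancy_curve(sites, asm, [1_000])
        assert strict.determined_windows.tolist() == [1]
        loose = occupancy_curve(sites, asm, [1_000], include_unmapped=True)
        assert loose.determined_windows.tolist() == [2]


class TestInformativeFraction:
    def _table(self):
        # 92 genotyped variants, 24 singletons; 57 discovered from domestic
        # cats of which 50 are multi-cat.
        rows = []
        for i in range(57):
            carriers = 2 if i < 50 else 1
            rows.append({"carriers": carriers, "discovered_in": "Pixel"})
        for i in range(35):
            carriers = 1 if i < (24 - 7) else 2
            rows.append({"carriers": carriers, "discovered_in": "Nancy"})
        return pd.DataFrame(rows)

    def test_published_fractions(self):
        rep = informative_fraction(self._table())
        assert (rep.total, rep.singletons) == (92, 24)
        assert (rep.singleton_pct, rep.multi_pct) == (26, 74)

    def test_domestic_restricted_fraction_and_extrapolation(self):
        rep = informative_fraction(
            self._table(),
            restrict_to_domestic=True,
            extrapolation_base=published.GENOME_TOTAL[2],
            domestic=published.DOMESTIC_BREED_CATS,
        )
        assert rep.total == 57 and rep.multi_cat == 50
        assert rep.multi_pct == 88
        assert rep.extrapolated == 849_000

    def test_all_multi_is_100(self):
        table = pd.DataFrame({"carriers": [2, 3, 4], "discovered_in": ["Pixel"] * 3})
        rep = informative_fraction(table)
        assert rep.multi_pct == 100 and rep.singleton_pct == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            informative_fraction(pd.DataFrame({"carriers": []}))


class TestN50:
    @pytest.mark.parametrize("lengths,want", [([1], 1), ([5, 4, 3, 2, 1], 4)])
    def test_known_values(self, lengths, want):
        assert n50(lengths) == want

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_scan_oracle(self, lengths):
        assert n50(lengths) == oracle_n50(lengths)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])


class TestHomozygousFractionEstimator:
    def test_uniform_density_estimates_near_zero(self):
        length = 2_000_000
        asm = ReferenceAssembly({"chr1": "A" * length})
        rng = np.random.default_rng(31)
        sites = [
            site("chr1", int(p), {"Cinnamon"})
            for p in sorted(rng.integers(0, length, size=3_000))
        ]
        est = estimate_homozygous_fraction(sites, "Cinnamon", asm)
        assert est <= 0.10

    def test_no_calls_gives_nan(self):
        asm = ReferenceAssembly({"chr1": "A" * 100_000})
        assert np.isnan(estimate_homozygous_fraction([], "Cinnamon", asm))
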