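"""Cross-species matching, Venn partitioning, regime labels, host ranges."""

import numpy as np
import pandas as pd
import pytest

from mosvirome import (
    MatchParams, PairwiseIdentity, Regime, ValidationError,
    cross_species_match, dissimilarity_regime, host_range_summary,
    known_virus_flag, partition_presence,
)
from mosvirome.vtu import assign_vtus
from conftest import make_contig


def _vtu(species, cids):
    return assign_vtus([make_contig(cid=c, species=species) for c in cids])[0]


class TestCrossSpeciesMatch:
    def _hosts(self):
        return {
            "Culex a": [_vtu("Virus X", ["a1", "a2"])],
            "Culex b": [_vtu("Virus X", ["b1"])],
        }

    @pytest.mark.parametrize("pid,merged", [(80.1, True), (80.0, False)])
    def test_identity_boundary_strictly_above_80(self, pid, merged):
        table = cross_species_match(
            self._hosts(), [PairwiseIdentity("a2", "b1", pid)])
        if merged:
            assert len(table) == 1 and table.iloc[0][["Culex a", "Culex b"]].sum() == 2
        else:
            assert len(table) == 2 and not table["merged"].any()

    def test_absent_pair_is_no_evidence(self):
        table = cross_species_match(self._hosts(), [])
        assert len(table) == 2

    def test_symmetric_in_host_and_input_order(self, rng):
        hosts = self._hosts()
        idents = [PairwiseIdentity("a1", "b1", 92.0),
                  PairwiseIdentity("a2", "b1", 60.0)]
        t1 = cross_species_match(hosts, idents)
        t2 = cross_species_match(dict(reversed(list(hosts.items()))), idents[::-1])
        assert t1.sort_index(axis=1).equals(t2.sort_index(axis=1))

    def test_out_of_range_identity_rejected(self):
        with pytest.raises(ValidationError):
            PairwiseIdentity("a", "b", 101.0)

    def test_matches_brute_force_any_pair_scan(self, rng):
        hosts = {}
        contig_of_host = {}
        for h in ("H1", "H2", "H3"):
            cids = [f"{h}_c{i}" for i in range(4)]
            hosts[h] = [_vtu("Virus Z", cids)]
            contig_of_host[h] = cids
        idents = []
        for _ in range(30):
            ha, hb = rng.choice(["H1", "H2", "H3"], size=2, replace=False)
            idents.append(PairwiseIdentity(
                str(rng.choice(contig_of_host[ha])),
                str(rng.choice(contig_of_host[hb])),
                float(rng.uniform(60, 100))))
        table = cross_species_match(hosts, idents)
        # brute force: hosts linked iff any cross pair > 80; components by flood fill
        adj = {(ha, hb): any(
            rec.percent_identity_nt > 80 and
            ((rec.contig_a in contig_of_host[ha] and rec.contig_b in contig_of_host[hb]) or
             (rec.contig_b in contig_of_host[ha] and rec.contig_a in contig_of_host[hb]))
            for rec in idents)
            for ha in hosts for hb in hosts if ha < hb}
        # flood fill components
        comps = []
        seen = set()
        for h in hosts:
            if h in seen:
                continue
            stack, comp = [h], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                for y in hosts:
                    if y not in comp and adj.get(tuple(sorted((x, y))), False):
                        stack.append(y)
            comps.append(comp)
            seen |= comp
        assert len(table) == len(comps)
        got_groups = sorted(
            tuple(sorted(h for h in hosts if row[h])) for _, row in table.iterrows())
        assert got_groups == sorted(tuple(sorted(c)) for c in comps)


class TestKnownVirusFlag:
    @pytest.mark.parametrize("pid,cov,expected", [
        (85.0, 95.0, True),
        (85.0, 89.9, False),   # coverage floor is >= 90
        (79.0, 100.0, False),  # identity must exceed 80
        (80.0, 100.0, False),  # strictly above
    ])
    def test_thresholds(self, pid, cov, expected):
        v = _vtu("Virus K", ["k1", "k2"])
        refs = [PairwiseIdentity("k1", "ref|Virus K", pid, cov)]
        assert known_virus_flag(v, refs) is expected

    def test_unrelated_contig_ignored(self):
        v = _vtu("Virus K", ["k1"])
        refs = [PairwiseIdentity("zz", "ref|Virus K", 99.0, 99.0)]
        assert known_virus_flag(v, refs) is False


class TestPartitionPresence:
    def test_three_singletons(self):
        df = pd.DataFrame(np.eye(3, dtype=int), index=list("xyz"),
                          columns=["A", "B", "C"])
        out = partition_presence(df)
        counts = dict(zip(out["region"], out["count"]))
        assert counts["A"] == counts["B"] == counts["C"] == 1
        assert counts["A&B&C"] == 0

    def test_all_shared(self):
        df = pd.DataFrame(1, index=list("xyz"), columns=["A", "B", "C"])
        out = partition_presence(df)
        counts = dict(zip(out["region"], out["count"]))
        assert counts["A&B&C"] == 3
        assert sum(counts.values()) == 3

    def test_regions_partition_random_tables(self, rng):
        for _ in range(10):
            df = pd.DataFrame(rng.integers(0, 2, size=(25, 3)),
                              columns=["A", "B", "C"])
            out = partition_presence(df)
            assert out["count"].sum() == int((df.sum(axis=1) > 0).sum())
            # brute force one region: taxa exactly in A and B but not C
            expected = int(((df["A"] == 1) & (df["B"] == 1) & (df["C"] == 0)).sum())
            got = out.loc[out["region"] == "A&B", "count"].iloc[0]
            assert got == expected

    def test_too_many_levels_rejected(self):
        df = pd.DataFrame(1, index=["x"], columns=list("ABCD"))
        with pytest.raises(ValueError):
            partition_presence(df)


class TestRegime:
    @pytest.mark.parametrize("sor,bc,expected", [
        (0.15, 0.69, Regime.ABUNDANCE_DOMINATED),
        (0.49, 0.86, Regime.ABUNDANCE_DOMINATED),
        (0.2, 0.3, Regime.MIXED),
        (0.6, 0.9, Regime.DIVERSITY_DOMINATED),
    ])
    def test_classification(self, sor, bc, expected):
        assert dissimilarity_regime(sor, bc) == expected

    def test_monotone_in_bray_curtis(self, rng):
        for _ in range(50):
            sor = float(rng.uniform(0, 0.49))
            bc1, bc2 = sorted(rng.uniform(0, 1, size=2))
            r1 = dissimilarity_regime(sor, bc1)
            r2 = dissimilarity_regime(sor, bc2)
            # raising Bray-Curtis can only move mixed -> abundance_dominated
            if r1 == Regime.ABUNDANCE_DOMINATED:
                assert r2 == Regime.ABUNDANCE_DOMINATED

    def test_range_validated(self):
        with pytest.raises(ValueError):
            dissimilarity_regime(1.2, 0.5)


class TestHostRangeSummary:
    def test_single_record(self):
        df = pd.DataFrame([{"virus": "v", "mosquito_species": "Culex x",
                            "mosquito_genus": "Culex", "country": "Senegal",
                            "continent": "Africa"}])
        per_virus, medians = host_range_summary(df)
        assert (per_virus.loc["v"] == 1).all()
        assert medians["median_n_species"] == 1

    def test_even_count_median_is_midpoint(self):
        rows = []
        for i in range(2):
            rows.append({"virus": "v1", "mosquito_species": f"s{i}",
                         "mosquito_genus": "g", "country": "c", "continent": "Af"})
        for i in range(6):
            rows.append({"virus": "v2", "mosquito_species": f"s{i}",
                         "mosquito_genus": "g", "country": "c", "continent": "Af"})
        _, medians = host_range_summary(pd.DataFrame(rows))
        assert medians["median_n_species"] == 4.0

    def test_matches_distinct_count_enumeration(self, rng):
        rows = []
        for _ in range(200):
            rows.append({
                "virus": f"v{rng.integers(0, 8)}",
                "mosquito_species": f"s{rng.integers(0, 15)}",
                "mosquito_genus": f"g{rng.integers(0, 4)}",
                "country": f"c{rng.integers(0, 10)}",
                "continent": f"k{rng.integers(0, 5)}"})
        df = pd.DataFrame(rows)
        per_virus, _ = host_range_summary(df)
        for virus, grp in df.groupby("virus"):
            assert per_virus.loc[virus, "n_species"] == grp["mosquito_species"].nunique()
            assert per_virus.loc[virus, "n_countries"] == grp["country"].nunique()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            host_range_summary(pd.DataFrame(
                columns=["virus", "mosquito_species", "mosquito_genus",
                         "country", "continent"]))
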