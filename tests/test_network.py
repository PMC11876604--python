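from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmecomm.network import (
    adjust_pvalues,
    bootstrap_network_test,
    differential_lr_test,
    export_network,
)


def _cbar_table(values: dict[str, float]) -> pd.DataFrame:
    """One directed pair, one sample per tumor."""
    return pd.DataFrame(
        {
            "sample": list(values),
            "sender": "Cancer",
            "receiver": "Myeloid",
            "cbar": list(values.values()),
        }
    )


def exhaustive_permutation_oracle(values: np.ndarray, is_res: np.ndarray) -> float:
    """Independent enumeration of all label assignments (rank p-value)."""
    n, k = len(values), int(is_res.sum())
    obs = values[is_res].mean() - values[~is_res].mean()
    count, total = 0, 0
    for idx in combinations(range(n), k):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        diff = values[mask].mean() - values[~mask].mean()
        count += abs(diff) >= abs(obs)
        total += 1
    return count / total


class TestBootstrapNetworkTest:
    def test_identical_networks_give_p_one(self):
        vals = {f"T{i}": 1.5 for i in range(6)}
        labels = pd.Series(
            ["resistant"] * 3 + ["sensitive"] * 3, index=[f"T{i}" for i in range(6)]
        )
        res = bootstrap_network_test(_cbar_table(vals), labels, B=200, seed=0)
        row = res.loc[("Cancer", "Myeloid")]
        assert row["obs_diff"] == 0.0
        assert row["p"] == 1.0

    def test_matches_exhaustive_oracle_on_six_tumors(self, rng):
        """Enumerated mode reproduces an independent all-assignments oracle."""
        for trial in range(5):
            vals = dict(zip([f"T{i}" for i in range(6)], rng.normal(size=6)))
            labels = pd.Series(
                ["resistant"] * 3 + ["sensitive"] * 3, index=list(vals)
            )
            res = bootstrap_network_test(_cbar_table(vals), labels, B=20, seed=trial)
            expected = exhaustive_permutation_oracle(
                np.array(list(vals.values())), np.array([True] * 3 + [False] * 3)
            )
            assert res.loc[("Cancer", "Myeloid"), "p"] == pytest.approx(expected)
            assert res.loc[("Cancer", "Myeloid"), "B"] == 20

    def test_z_antisymmetric_under_label_swap(self, rng):
        vals = dict(zip([f"T{i}" for i in range(8)], rng.normal(size=8)))
        lab = ["resistant"] * 4 + ["sensitive"] * 4
        labels = pd.Series(lab, index=list(vals))
        flipped = pd.Series(
            ["sensitive" if l == "resistant" else "resistant" for l in lab],
            index=list(vals),
        )
        a = bootstrap_network_test(_cbar_table(vals), labels, B=300, seed=5)
        b = bootstrap_network_test(_cbar_table(vals), flipped, B=300, seed=5)
        za, zb = a.loc[("Cancer", "Myeloid"), "z"], b.loc[("Cancer", "Myeloid"), "z"]
        assert za == pytest.approx(-zb, rel=0.15)
        assert a.loc[("Cancer", "Myeloid"), "obs_diff"] == pytest.approx(
            -b.loc[("Cancer", "Myeloid"), "obs_diff"]
        )

    def test_multiple_timepoints_shuffle_as_one_tumor(self, rng):
        # two samples per tumor must move together under the shuffle
        samples, tumors, cbar = [], {}, []
        for i in range(6):
            for d in (0, 14):
                s = f"T{i}_d{d}"
                samples.append(s)
                tumors[s] = f"T{i}"
                cbar.append(rng.normal())
        table = pd.DataFrame(
            {"sample": samples, "sender": "A", "receiver": "B", "cbar": cbar}
        )
        labels = pd.Series(
            ["resistant"] * 3 + ["sensitive"] * 3, index=[f"T{i}" for i in range(6)]
        )
        res = bootstrap_network_test(
            table, labels, patients=pd.Series(tumors), B=20, seed=0
        )
        per_tumor = table.assign(t=table["sample"].map(tumors)).groupby("t")["cbar"].mean()
        expected = exhaustive_permutation_oracle(
            per_tumor.to_numpy(), np.array([True] * 3 + [False] * 3)
        )
        assert res.loc[("A", "B"), "p"] == pytest.approx(expected)

    def test_empty_group_rejected(self):
        vals = {f"T{i}": 0.5 for i in range(4)}
        labels = pd.Series(["resistant"] * 4, index=list(vals))
        with pytest.raises(ValueError, match="per group"):
            bootstrap_network_test(_cbar_table(vals), labels, B=200)

    def test_low_B_warns(self, rng):
        vals = dict(zip([f"T{i}" for i in range(6)], rng.normal(size=6)))
        labels = pd.Series(["resistant"] * 3 + ["sensitive"] * 3, index=list(vals))
        with pytest.warns(UserWarning, match="randomizations is low"):
            bootstrap_network_test(_cbar_table(vals), labels, B=50, exhaustive=False)


class TestPvalueAdjustment:
    def test_holm_closed_form(self):
        assert np.allclose(adjust_pvalues([0.01, 0.04], "holm"), [0.02, 0.04])

    def test_bh_closed_form(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03])

    def test_empty_list(self):
        assert len(adjust_pvalues([], "holm")) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_pvalues([0.5, 1.2], "bh")

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25),
        st.sampled_from(["holm", "bh"]),
    )
    def test_matches_statsmodels(self, pvals, method):
        """Independent cross-check against the reference implementation."""
        from statsmodels.stats.multitest import multipletests

        ours = adjust_pvalues(pvals, method)
        sm_method = {"holm": "holm", "bh": "fdr_bh"}[method]
        theirs = multipletests(pvals, method=sm_method)[1]
        assert np.allclose(ours, theirs, atol=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)


class TestDifferentialLR:
    @staticmethod
    def _toy_tensor(n_per_group, effect, seed=0, n_pathways=4):
        import xarray as xr

        rng = np.random.default_rng(seed)
        samples = [f"T{i}" for i in range(2 * n_per_group)]
        data = rng.lognormal(3.0, 0.3, size=(len(samples), 1, 1, n_pathways))
        data[:n_per_group, :, :, 0] *= np.exp(effect)
        arr = xr.DataArray(
            data,
            dims=("sample", "sender", "receiver", "pathway"),
            coords={
                "sample": samples,
                "sender": ["Cancer"],
                "receiver": ["Myeloid"],
                "pathway": [f"p{k}" for k in range(n_pathways)],
            },
        )
        from tmecomm.communication import CommunicationTensor

        labels = pd.Series(
            ["resistant"] * n_per_group + ["sensitive"] * n_per_group, index=samples
        )
        return CommunicationTensor(raw=arr), labels

    def test_strong_effect_detected_with_fdr(self):
        tensor, labels = self._toy_tensor(10, effect=1.5, seed=1)
        res = differential_lr_test(tensor, labels, sender="Cancer", receiver="Myeloid")
        assert res.loc["p0", "q"] < 0.05
        assert res.loc["p0", "est"] > 0

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        pvals = []
        for seed in range(100):
            tensor, labels = self._toy_tensor(5, effect=0.0, seed=seed, n_pathways=1)
            res = differential_lr_test(tensor, labels, sender="Cancer", receiver="Myeloid")
            pvals.append(res["p"].iloc[0])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_all_zero_group_stays_finite(self):
        tensor, labels = self._toy_tensor(3, effect=0.0, seed=2)
        tensor.raw.values[:3, :, :, 0] = 0.0
        res = differential_lr_test(tensor, labels, sender="Cancer", receiver="Myeloid")
        assert np.isfinite(res.loc["p0", "t"])
        assert np.isfinite(res.loc["p0", "p"])


class TestExportNetwork:
    def test_strong_edge_threshold(self):
        summary = pd.DataFrame(
            {
                "sender": ["A", "A", "B", "B"],
                "receiver": ["A", "B", "A", "B"],
                "weight": [1.0, 1.0, 1.0, 4.0],
            }
        )
        edges = export_network(summary)
        # mean 1.75, sd 1.5 -> threshold 3.25: only the weight-4 edge
        assert edges["strong"].sum() == 1
        assert edges.loc[edges["strong"], "weight"].iloc[0] == 4.0

    def test_equal_weights_have_no_strong_edges(self):
        summary = pd.DataFrame(
            {"sender": ["A", "B"], "receiver": ["B", "A"], "weight": [2.0, 2.0]}
        )
        assert export_network(summary)["strong"].sum() == 0

    def test_shift_invariance_of_strong_set(self, rng):
        w = rng.normal(size=10)
        summary = pd.DataFrame(
            {"sender": "A", "receiver": [f"R{i}" for i in range(10)], "weight": w}
        )
        shifted = summary.assign(weight=w + 100.0)
        assert (
            export_network(summary)["strong"].tolist()
            == export_network(shifted)["strong"].tolist()
        )
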