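import numpy as np
import pandas as pd
import pytest

from refstab.io import CqMatrix
from refstab.preprocess import relative_quantities
from refstab.simulate import SimulationSpec, generate_cq
from refstab.validate import normalize_targets, panel_contrast

from conftest import make_cq


def split_targets(cq, target_genes):
    """Partition one matrix into reference and target CqMatrix views."""
    refs = [g for g in cq.gene_ids if g not in target_genes]
    return cq.select(genes=refs), cq.select(genes=list(target_genes))


class TestNormalizeTargets:
    def test_target_identical_to_single_panel_gene_is_flat_one(self, pbmc):
        target = CqMatrix(
            pbmc.data[["RPS9"]].rename(columns={"RPS9": "T1"}), pbmc.groups
        )
        rq = relative_quantities(pbmc)
        out = normalize_targets(target, ["RPS9"], rq)
        assert np.allclose(out["T1"].expression, 1.0)

    def test_constant_cycle_offset_is_a_constant_fold(self, pbmc):
        target = CqMatrix(
            (pbmc.data[["RPS9"]] - 1.0).rename(columns={"RPS9": "T1"}), pbmc.groups
        )
        rq = relative_quantities(pbmc)
        out = normalize_targets(target, ["RPS9"], rq)
        # one cycle below the panel gene everywhere -> constant expression;
        # both target and panel RQ are anchored at their own minimum, so the
        # offset cancels and the ratio is exactly 1 under E = 2
        assert np.allclose(out["T1"].expression, 1.0)
        assert out["T1"].fold_difference == pytest.approx(1.0)

    def test_se_times_sqrt_n_equals_sd(self, pbmc):
        refs, targets = split_targets(pbmc, ["ACTB"])
        out = normalize_targets(targets, ["RPS9", "RPS15"], relative_quantities(refs))
        summ = out["ACTB"].summary
        assert np.allclose(summ["se"] * np.sqrt(summ["n"]), summ["sd"])

    def test_overlap_between_targets_and_panel_rejected(self, pbmc):
        rq = relative_quantities(pbmc)
        target = pbmc.select(genes=["RPS9"])
        with pytest.raises(ValueError, match="overlap"):
            normalize_targets(target, ["RPS9", "RPS15"], rq)

    def test_unknown_panel_gene_rejected(self, pbmc):
        refs, targets = split_targets(pbmc, ["ACTB"])
        with pytest.raises(ValueError, match="absent"):
            normalize_targets(targets, ["NOPE"], relative_quantities(refs))

    def test_twofold_group_difference_recovered_from_simulation(self):
        hits = 0
        for seed in range(50):
            genes = {f"r{j}": 20.0 for j in range(4)}
            genes["target"] = 24.0
            spec = SimulationSpec(
                groups={"a": 15, "b": 15},
                baseline_cq=genes,
                noise_sd={g: 0.3 for g in genes},
                # -1 cycle in group a = 2-fold higher target expression
                group_shift={"target": {"a": -0.5, "b": +0.5}},
                seed=seed,
            )
            cq, _ = generate_cq(spec)
            refs, targets = split_targets(cq, ["target"])
            out = normalize_targets(targets, ["r0", "r1", "r2"],
                                    relative_quantities(refs))
            if 1.6 <= out["target"].fold_difference <= 2.5:
                hits += 1
        assert hits >= 40


class TestPanelContrast:
    def test_identical_panels_are_identical_and_unreversed(self, pbmc):
        refs, targets = split_targets(pbmc, ["ACTB"])
        rq = relative_quantities(refs)
        out = panel_contrast(targets, ["RPS9", "RPS15"], ["RPS9", "RPS15"], rq)
        c = out["ACTB"]
        assert not c.reversal
        assert np.allclose(c.best.expression, c.worst.expression)

    def test_confounded_worst_panel_reverses_the_direction(self):
        genes = {f"r{j}": 20.0 for j in range(4)}
        genes["bad"] = 22.0
        genes["target"] = 24.0
        spec = SimulationSpec(
            groups={"a": 15, "b": 15},
            baseline_cq=genes,
            noise_sd={g: 0.1 for g in genes},
            group_shift={
                # the target is truly up in group a...
                "target": {"a": -0.75, "b": +0.75},
                # ...and the bad reference shifts twice as far the same way
                "bad": {"a": -1.5, "b": +1.5},
            },
            seed=42,
        )
        cq, _ = generate_cq(spec)
        refs, targets = split_targets(cq, ["target"])
        rq = relative_quantities(refs)
        out = panel_contrast(targets, ["r0", "r1", "r2"], ["bad"], rq)
        c = out["target"]
        assert c.best.fold_difference > 1.5
        assert c.worst.fold_difference < 1.0
        assert c.reversal

    def test_null_target_with_stable_panels_rarely_reverses(self):
        no_reversal = 0
        for seed in range(100):
            genes = {f"r{j}": 20.0 for j in range(4)}
            genes["target"] = 24.0
            spec = SimulationSpec(
                groups={"a": 15, "b": 15},
                baseline_cq=genes,
                noise_sd={g: 0.3 for g in genes},
                seed=seed,
            )
            cq, _ = generate_cq(spec)
            refs, targets = split_targets(cq, ["target"])
            rq = relative_quantities(refs)
            out = panel_contrast(targets, ["r0", "r1"], ["r2", "r3"], rq)
            c = out["target"]
            if not c.reversal and abs(np.log2(c.best.fold_difference)) < 0.5:
                no_reversal += 1
        assert no_reversal >= 90

    def test_stable_panel_variance_not_worse_than_noisy_panel(self):
        better = 0
        for seed in range(30):
            genes = {"good1": 20.0, "good2": 21.0, "noisy1": 20.0, "noisy2": 21.0,
                     "target": 24.0}
            spec = SimulationSpec(
                groups={"a": 15, "b": 15},
                baseline_cq=genes,
                noise_sd={"good1": 0.1, "good2": 0.1, "noisy1": 1.0, "noisy2": 1.0,
                          "target": 0.1},
                seed=seed,
            )
            cq, _ = generate_cq(spec)
            refs, targets = split_targets(cq, ["target"])
            rq = relative_quantities(refs)
            out = panel_contrast(
                targets, ["good1", "good2"], ["noisy1", "noisy2"], rq
            )
            c = out["target"]
            var_best = np.log2(c.best.expression).var()
            var_worst = np.log2(c.worst.expression).var()
            if var_best <= var_worst:
                better += 1
        assert better >= 27
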