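"""Benchmark scenarios used for validating the pipeline on simulated truth.

Each scenario wires the generator to the downstream statistics at a scale a
single CPU handles in minutes:

* ``fdp_trial`` - the spiked experiment (2,000 unlinked loci, 200 drivers at
  s = 0.15, Ne = 1,000, pools of 100 at 80x, generations 4 and 17): run the
  divergence scan and measure the realized false-discovery proportion among
  SDV against the known driver set.
* ``null_pvalue_trial`` - the same experiment with no drivers: return the
  observed GLMM p-values for uniformity checks.
* ``driver_recovery_trial`` - one strong driver (s = 0.3) on a
  low-recombination arm: ask whether the window scan recovers a block
  containing the driver and whether the driver is that block's top variant.
  The driver is the mid-arm site with founder frequency closest to 0.25,
  matching selection on common standing variation.
* ``selection_expectation_trial`` - many replicates of a single driver at
  large Ne against the deterministic one-locus recursion.
"""

from __future__ import annotations

import numpy as np

from . import blocks as blocks_mod
from .filtering import filter_pipeline
from .glmm import run_divergence_scan
from .simulate import (SimulationConfig, build_founders, evolve_population,
                       generate_experiment, selection_recursion)


def spiked_config(seed: int, n_loci: int = 2000, n_drivers: int = 200,
                  s: float = 0.15, ne: int = 1000,
                  depth: float = 80.0) -> SimulationConfig:
    """The spiked unlinked-loci experiment; drivers evenly spaced."""
    stride = max(n_loci // n_drivers, 1)
    drivers = tuple((i, s, 0.5) for i in range(0, stride * n_drivers, stride))
    return SimulationConfig(
        n_loci=n_loci, ne=ne, arms=(("2L", 20_000_000),),
        free_recombination=True, founder_mode="linkage_equilibrium",
        driver_loci=drivers, pool_individuals=100, depth_mean=depth,
        seed=seed)


def null_config(seed: int, n_loci: int = 2000, ne: int = 1000,
                depth: float = 80.0) -> SimulationConfig:
    return SimulationConfig(
        n_loci=n_loci, ne=ne, arms=(("2L", 20_000_000),),
        free_recombination=True, founder_mode="linkage_equilibrium",
        pool_individuals=100, depth_mean=depth, seed=seed)


def _scan_experiment(config: SimulationConfig, alpha: float = 0.05):
    table, design, truth, founders = generate_experiment(config)
    bial, _ = filter_pipeline(table, design)
    scan = run_divergence_scan(bial, design, alpha=alpha)
    return scan, truth, founders


def fdp_trial(seed: int, alpha: float = 0.05, **cfg_kw) -> dict:
    """Run the spiked experiment; count called SDV and false calls."""
    config = spiked_config(seed, **cfg_kw)
    scan, truth, founders = _scan_experiment(config, alpha)
    res = scan.results
    driver_pos = set(founders.positions[truth.driver_sites].tolist())
    called = res[res["sdv"]]
    n_called = len(called)
    n_false = int((~called["pos"].isin(driver_pos)).sum())
    return {"seed": seed, "n_called": n_called, "n_false": n_false,
            "threshold": scan.threshold, "n_tested": len(res)}


def null_pvalue_trial(seed: int, **cfg_kw) -> np.ndarray:
    """Observed GLMM p-values under the no-driver experiment."""
    config = null_config(seed, **cfg_kw)
    scan, _, _ = _scan_experiment(config)
    return scan.results["p"].to_numpy()


def _pick_common_mid_arm_site(founders, target_freq: float = 0.25):
    freqs = founders.founder_frequencies
    centre = (founders.positions.min() + founders.positions.max()) / 2
    # prefer frequency near target, break ties toward the arm centre
    score = (np.abs(freqs - target_freq)
             + np.abs(founders.positions - centre) / 1e9)
    return int(np.argmin(score))


def driver_recovery_trial(seed: int, s: float = 0.3, n_loci: int = 2300,
                          ne: int = 1000, depth: float = 80.0,
                          recomb_rate: float = 1e-8) -> dict:
    """Single strong driver on a linked arm: block and top-variant recovery.

    The arm is chromosome-arm-sized (23 Mb) so that, at a realistic fly
    crossover rate, founder LD with the driver decays across the arm over
    17 generations and the sweep leaves a spatially localized block rather
    than repainting the whole arm.
    """
    base = SimulationConfig(
        n_loci=n_loci, ne=ne, arms=(("2L", 23_000_000),),
        recomb_rate=recomb_rate, pool_individuals=100,
        depth_mean=depth, seed=seed)
    # founders are reproducible: the same seed stream is used inside
    # generate_experiment, and driver placement does not perturb it
    root = np.random.SeedSequence(base.seed)
    streams = root.spawn(1 + 2 * base.n_replicates_per_treatment)
    founders = build_founders(base, np.random.default_rng(streams[0]))
    driver = _pick_common_mid_arm_site(founders)
    config = SimulationConfig(
        **{**base.__dict__, "driver_loci": ((driver, s, 0.5),)})
    scan, truth, founders = _scan_experiment(config)
    driver_pos = int(founders.positions[driver])

    # windows sized to marker density: at ~1 locus per 10 kb, 500-kb windows
    # hold ~50 variants, comparable per-window counts to a dense study's
    # 50-kb windows
    windows = blocks_mod.scan_windows(scan.results, window=500_000,
                                      step=100_000)
    windows = blocks_mod.adjust_windows(windows, alpha=0.05)
    blocks = blocks_mod.consolidate_blocks(windows)
    in_block = None
    for b in blocks:
        if b.start <= driver_pos - 1 < b.end:
            in_block = b
            break
    top_is_driver = False
    if in_block is not None:
        res = scan.results
        pos0 = res["pos"].to_numpy() - 1
        inside = ((res["arm"] == in_block.arm).to_numpy()
                  & (pos0 >= in_block.start) & (pos0 < in_block.end)
                  & res["sdv"].to_numpy())
        sub = res[inside]
        if len(sub):
            top = sub[sub["p"] == sub["p"].min()]
            top_is_driver = bool((top["pos"] == driver_pos).any())
    return {"seed": seed, "driver_pos": driver_pos,
            "n_blocks": len(blocks), "block_found": in_block is not None,
            "top_is_driver": top_is_driver}


def selection_expectation_trial(seed: int, n_replicates: int = 200,
                                ne: int = 10_000, s: float = 0.5,
                                h: float = 0.5, generations: int = 17
                                ) -> dict:
    """Mean simulated driver trajectory vs the deterministic recursion."""
    config = SimulationConfig(
        n_loci=1, ne=ne, arms=(("2L", 1000),), line_identity=0.0,
        sfs="uniform", sampled_generations=(generations,),
        driver_loci=((0, s, h),), pool_individuals=100, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    founders = build_founders(config, rng)
    half = founders.haplotypes.shape[0] // 2
    founders.haplotypes[:half] = 1          # start exactly at 0.5
    founders.haplotypes[half:] = 0
    finals = np.empty(n_replicates)
    for i in range(n_replicates):
        traj = evolve_population(
            founders, config, selected=True,
            rng=np.random.default_rng(np.random.SeedSequence((seed, i))),
            record_populations=False)
        finals[i] = traj.freqs[generations][0]
    expected = selection_recursion(0.5, s, h, generations)
    return {"mean": float(finals.mean()), "expected": float(expected),
            "mc_se": float(finals.std(ddof=1) / np.sqrt(n_replicates))}
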