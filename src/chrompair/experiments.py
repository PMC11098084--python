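"""Preset scenario runner: each figure-level experiment from one command.

A scenario is a named list of conditions; every condition fully specifies a
configuration and the barcodes carried by each chain.  The runner executes an
ensemble of independently seeded runs per condition, writes per-run metrics
(CSV), an ensemble summary (JSON) and a figure-style plot (PNG), and is fully
determined by (scenario, overrides, base_seed).  Default ensembles follow the
standard protocol of 30 runs × 300,000 iterations; pass ``n_runs``/``n_steps``
overrides for desk-scale replicas.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import (
    chance_baseline,
    ensemble_summary,
    estimate_persistence_length,
    final_fidelity,
    kymograph,
    partner_breakdown,
    rabl_correlation,
    save_kymograph,
    time_to_fraction_paired,
)
from .barcode import (
    Barcode,
    encode_2of5,
    gaps_to_barcode,
    random_barcode,
    reciprocal_translocation,
    shift_barcode,
    uniform_barcode,
)
from .config import SimulationConfig
from .dynamics_engine import run

__all__ = [
    "run_scenario",
    "run_ensemble",
    "available_scenarios",
    "best_five_code",
    "five_button_code",
    "Condition",
]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def best_five_code(arm_length: int = 48) -> Barcode:
    """The named five-button reference code: a random code clustered in the
    13-node centromere-proximal stretch, generated from a fixed documented
    seed so shift/translocation experiments have a stable fixture."""
    return random_barcode(5, (0, 12), _rng(50, 0), arm_length=arm_length)


def five_button_code(index: int, arm_length: int = 48) -> Barcode:
    """Additional seeded five-button codes in the same 13-node stretch."""
    return random_barcode(5, (0, 12), _rng(50, 1 + index), arm_length=arm_length)


@dataclass
class Condition:
    label: str
    config: SimulationConfig
    barcodes: list  # per pair or per chain
    x: float | None = None  # numeric x-axis value for curve plots
    extras: dict = field(default_factory=dict)


def run_ensemble(
    config: SimulationConfig,
    barcodes=None,
    n_runs: int = 30,
    base_seed: int = 0,
    mode: str = "locus",
    pairing_enabled: bool = True,
    keep_trajectories: bool = False,
):
    """Ensemble of independently seeded runs; per-run metric lists."""
    out = {
        "fidelity": [],
        "fidelity_chromosome": [],
        "time_to_90pct": [],
        "breakdown": [],
        "trajectories": [],
    }
    for r in range(n_runs):
        cfg = config.replace(seed=int(base_seed + r))
        traj = run(cfg, barcodes=barcodes, pairing_enabled=pairing_enabled)
        out["fidelity"].append(final_fidelity(traj, mode))
        out["fidelity_chromosome"].append(final_fidelity(traj, "chromosome"))
        t90 = time_to_fraction_paired(traj, 0.9, mode)
        out["time_to_90pct"].append(t90)
        out["breakdown"].append(partner_breakdown(traj))
        if keep_trajectories:
            out["trajectories"].append(traj)
    return out


def _uniform_3v4(cfg: SimulationConfig) -> list[Barcode]:
    return [
        uniform_barcode(3, cfg.nodes_per_arm),
        uniform_barcode(4, cfg.nodes_per_arm),
    ]


def _tract(spacing: int, center: int, n_buttons: int, arm: int) -> Barcode:
    span = (n_buttons - 1) * spacing
    start = center - span // 2
    return Barcode(tuple(start + i * spacing for i in range(n_buttons)), arm)


def _digit_pair_codes(d0: int, d1: int, arm: int, start: int = 0) -> list[Barcode]:
    return [
        gaps_to_barcode(encode_2of5(d0), start, arm),
        gaps_to_barcode(encode_2of5(d1), start, arm),
    ]


def _scn_fig2(cfg, ov):
    return [Condition("uniform 3 vs 4, whole arm", cfg, _uniform_3v4(cfg))]


def _scn_fig3b(cfg, ov):
    grid = ov.get("k_bend_grid", [0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0])
    arm = cfg.nodes_per_arm
    layouts = {
        "centered": [_tract(3, 20, 5, arm), _tract(4, 20, 5, arm)],
        "offset": [_tract(3, 9, 5, arm), _tract(4, 20, 5, arm)],
    }
    conds = []
    for layout, codes in layouts.items():
        for kb in grid:
            conds.append(
                Condition(
                    f"{layout} k_bend={kb:g}",
                    cfg.replace(k_bend=float(kb)),
                    codes,
                    x=float(kb),
                    extras={"layout": layout},
                )
            )
    return conds


def _scn_fig3c(cfg, ov):
    grid = ov.get("p_unpair_grid", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    return [
        Condition(
            f"p_unpair={p:g}",
            cfg.replace(p_unpair=float(p)),
            _uniform_3v4(cfg),
            x=float(p),
        )
        for p in grid
    ]


def _scn_fig3d(cfg, ov):
    grid = ov.get("rabl_grid", [2.0, 4.0, 8.0, 16.0, 2 * cfg.nucleus_radius])
    return [
        Condition(
            f"rabl_patch_radius={rp:g}",
            cfg.replace(rabl_patch_radius=float(rp)),
            _uniform_3v4(cfg),
            x=float(rp),
        )
        for rp in grid
    ]


def _scn_fig4(cfg, ov):
    densities = ov.get("densities", [5, 8, 13])
    per = int(ov.get("codes_per_density", 3))
    arm = cfg.nodes_per_arm
    conds = []
    for d in densities:
        for i in range(per):
            code = random_barcode(d, (0, arm - 1), _rng(40, d, i), arm_length=arm)
            conds.append(
                Condition(
                    f"random {d}-button code {i}",
                    cfg,
                    [code, random_barcode(d, (0, arm - 1), _rng(41, d, i), arm_length=arm)],
                    extras={"density": int(d)},
                )
            )
    return conds


def _scn_fig5a(cfg, ov):
    shifts = ov.get("shift_grid", list(range(0, 22, 2)))
    arm = cfg.nodes_per_arm
    codes = [best_five_code(arm), five_button_code(0, arm)]
    return [
        Condition(
            f"shift={s}",
            cfg,
            [shift_barcode(codes[0], s), shift_barcode(codes[1], s)],
            x=float(s),
        )
        for s in shifts
    ]


def _scn_fig5b(cfg, ov):
    arm = cfg.nodes_per_arm
    n_codes = int(ov.get("n_codes", 5))
    base = best_five_code(arm)
    conds = [
        Condition("original", cfg, [base, five_button_code(0, arm)], extras={"kind": "original"})
    ]
    for i in range(n_codes):
        conds.append(
            Condition(
                f"random-in-stretch {i}",
                cfg,
                [
                    random_barcode(5, (0, 12), _rng(51, i), arm_length=arm),
                    random_barcode(5, (0, 12), _rng(52, i), arm_length=arm),
                ],
                extras={"kind": "random"},
            )
        )
    return conds


def _scn_fig6(cfg, ov):
    arm = cfg.nodes_per_arm
    digit_pairs = ov.get("digit_pairs", [(0, 1), (3, 7), (4, 8)])
    n_random = int(ov.get("n_random", 5))
    conds = [
        Condition(
            f"2of5 {a} vs {b}",
            cfg,
            _digit_pair_codes(a, b, arm),
            extras={"kind": "2of5"},
        )
        for a, b in digit_pairs
    ]
    # random comparisons: same button count (6) and the same endpoints (span
    # 18 nodes from the centromeric end)
    for i in range(n_random):
        conds.append(
            Condition(
                f"random same-span {i}",
                cfg,
                [
                    random_barcode(6, (0, 18), _rng(60, i), arm_length=arm, fix_endpoints=True),
                    random_barcode(6, (0, 18), _rng(61, i), arm_length=arm, fix_endpoints=True),
                ],
                extras={"kind": "random"},
            )
        )
    return conds


def _scn_fig7(cfg, ov):
    grid = ov.get("n_pairs_grid", list(range(2, 11)))
    arm = cfg.nodes_per_arm
    conds = []
    for npairs in grid:
        codes = [best_five_code(arm)] + [
            five_button_code(p, arm) for p in range(int(npairs) - 1)
        ]
        conds.append(
            Condition(
                f"n_pairs={npairs}",
                cfg.replace(n_pairs=int(npairs)),
                codes,
                x=float(npairs),
                extras={"chance": chance_baseline(int(npairs))},
            )
        )
    return conds


def _scn_fig8d(cfg, ov):
    arm = cfg.nodes_per_arm
    shift = int(ov.get("shift", 12))
    a = best_five_code(arm)
    b = five_button_code(0, arm)
    a_shift = shift_barcode(a, shift)
    return [
        Condition("control", cfg, [a, b], extras={"zygosity": "none"}),
        Condition(
            "heterozygous shift",
            cfg,
            [a, a_shift, b, b],
            extras={"zygosity": "heterozygous"},
        ),
        Condition(
            "homozygous shift",
            cfg,
            [a_shift, a_shift, b, b],
            extras={"zygosity": "homozygous"},
        ),
    ]


def _scn_fig8e(cfg, ov):
    arm = cfg.nodes_per_arm
    a = best_five_code(arm)
    b = five_button_code(0, arm)
    patch = tuple(ov.get("patch", (0, 11)))  # 12-node barcode patch
    lo, hi = patch
    quarter = (hi - lo + 1) // 4
    conds = [Condition("control", cfg, [a, b], extras={"swap": "none"})]
    for q in range(4):
        ra = (lo + q * quarter, lo + (q + 1) * quarter - 1)
        a2, b2 = reciprocal_translocation(a, b, ra, ra)
        conds.append(
            Condition(
                f"quarter swap {q + 1}",
                cfg,
                [a, a2, b, b2],
                extras={"swap": f"quarter{q + 1}"},
            )
        )
    a2, b2 = reciprocal_translocation(a, b, patch, patch)
    conds.append(
        Condition("full patch swap", cfg, [a, a2, b, b2], extras={"swap": "full"})
    )
    return conds


_SCENARIOS = {
    "fig2": _scn_fig2,
    "fig3a": _scn_fig3b,  # same scan; panel A replots fidelity vs measured Lp
    "fig3b": _scn_fig3b,
    "fig3c": _scn_fig3c,
    "fig3d": _scn_fig3d,
    "fig4": _scn_fig4,
    "fig5a": _scn_fig5a,
    "fig5b": _scn_fig5b,
    "fig6": _scn_fig6,
    "fig7": _scn_fig7,
    "fig8d": _scn_fig8d,
    "fig8e": _scn_fig8e,
}

# scenarios whose conditions get a no-pairing calibration run
_CALIBRATED = {"fig3a": "persistence_length", "fig3d": "rabl_correlation"}


def available_scenarios() -> list[str]:
    return sorted(_SCENARIOS)


def run_scenario(
    name: str,
    out_dir=None,
    n_runs: int = 30,
    base_seed: int = 0,
    overrides: dict | None = None,
    mode: str = "locus",
    progress=None,
):
    """Run one preset scenario; returns (and optionally writes) its results.

    ``overrides`` may replace any SimulationConfig field (``n_steps`` being
    the usual desk-scale knob) and scenario grid keys (``p_unpair_grid``,
    ``k_bend_grid``, ``rabl_grid``, ``shift_grid``, ``n_pairs_grid``,
    ``densities``, ``codes_per_density``, ``digit_pairs``, ...).
    """
    if name not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}"
        )
    ov = dict(overrides or {})
    import dataclasses as _dc

    cfg_fields = {f.name for f in _dc.fields(SimulationConfig)}
    cfg_over = {k: ov.pop(k) for k in list(ov) if k in cfg_fields}
    cfg = SimulationConfig(**cfg_over)
    if cfg.n_steps < cfg.record_every:
        cfg = cfg.replace(record_every=max(1, cfg.n_steps or 1))
    conditions = _SCENARIOS[name](cfg, ov)

    results = {"scenario": name, "base_seed": base_seed, "n_runs": n_runs, "conditions": []}
    for ci, cond in enumerate(conditions):
        if progress is not None:
            progress(f"[{name}] condition {ci + 1}/{len(conditions)}: {cond.label}")
        seed0 = base_seed + 9973 * ci
        ens = run_ensemble(
            cond.config,
            barcodes=cond.barcodes,
            n_runs=n_runs,
            base_seed=seed0,
            mode=mode,
            keep_trajectories=(name == "fig2"),
        )
        entry = {
            "label": cond.label,
            "x": cond.x,
            "extras": cond.extras,
            "fidelity": ensemble_summary(ens["fidelity"]),
            "fidelity_chromosome": ensemble_summary(ens["fidelity_chromosome"]),
            "time_to_90pct": [t if t is not None else "not reached" for t in ens["time_to_90pct"]],
            "breakdown_mean": {
                k: float(np.mean([b[k] for b in ens["breakdown"]]))
                for k in ens["breakdown"][0]
            },
        }
        calib = _CALIBRATED.get(name)
        if calib:
            ctraj = run(
                cond.config.replace(
                    seed=seed0 + 777_000,
                    n_steps=int(ov.get("calibration_steps", 20_000)),
                    record_every=min(cond.config.record_every, 200),
                ),
                barcodes=cond.barcodes,
                pairing_enabled=False,
            )
            entry[calib] = (
                estimate_persistence_length(ctraj)
                if calib == "persistence_length"
                else rabl_correlation(ctraj)
            )
        if name == "fig2" and ens["trajectories"]:
            entry["kymograph_matrix"] = kymograph(ens["trajectories"][0]).tolist()
        results["conditions"].append(entry)

    if out_dir is not None:
        _write_outputs(results, Path(out_dir), mode)
    return results


def _write_outputs(results: dict, out_dir: Path, mode: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    name = results["scenario"]
    with open(out_dir / f"{name}_summary.json", "w") as fh:
        json.dump(results, fh, indent=2)
    # per-run table
    import pandas as pd

    rows = []
    for cond in results["conditions"]:
        for i, v in enumerate(cond["fidelity"]["values"]):
            rows.append(
                {
                    "condition": cond["label"],
                    "x": cond["x"],
                    "run": i,
                    "fidelity": v,
                    "fidelity_chromosome": cond["fidelity_chromosome"]["values"][i],
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / f"{name}_runs.csv", index=False)
    _plot(results, out_dir / f"{name}.png")
    for cond in results["conditions"]:
        if "kymograph_matrix" in cond:
            m = np.asarray(cond["kymograph_matrix"])
            save_kymograph(
                m,
                csv_path=out_dir / f"{name}_kymograph.csv",
                png_path=out_dir / f"{name}_kymograph.png",
            )


def _plot(results: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conds = results["conditions"]
    numeric = all(c["x"] is not None for c in conds)
    fig, ax = plt.subplots(figsize=(max(5, 0.9 * len(conds)), 4))
    if numeric and len({c["x"] for c in conds}) > 1:
        groups = {}
        for c in conds:
            groups.setdefault(c["extras"].get("layout", ""), []).append(c)
        for label, cs in groups.items():
            xs = [c["x"] for c in cs]
            ys = [c["fidelity"]["mean"] for c in cs]
            es = [c["fidelity"]["sem"] for c in cs]
            ax.errorbar(xs, ys, yerr=es, marker="o", capsize=3, label=label or None)
        if any(groups):
            ax.legend()
        ax.set_xlabel("condition value")
    else:
        data = [c["fidelity"]["values"] for c in conds]
        ax.boxplot(data, whis=1.5, tick_labels=[c["label"] for c in conds])
        rng = np.random.default_rng(0)
        for i, vals in enumerate(data, start=1):
            ax.plot(
                i + 0.08 * rng.standard_normal(len(vals)),
                vals,
                ".",
                alpha=0.6,
                markersize=4,
            )
        ax.tick_params(axis="x", rotation=60)
    ax.set_ylabel("pairing fidelity")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(results["scenario"])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
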