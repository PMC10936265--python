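"""The 2x4 lifting study: {human-only, human-with-exoskeleton} x
{LSQ tracking, CLBL, PLBL, HYB cost}.

For each model variant the tracking (LSQ) problem reconstructs the
reference lift; the three predictive problems are warm-started from the
tracking solution (which is feasible for them), so their own cost can
never end above the cost evaluated on the tracked motion.  For the
exoskeleton variant each predictive problem is additionally warm-started
from the matching human-only predictive solution (zero exo control
appended) and the better of the two runs is kept.

Reported per block: the analysis-side CLBL (N m s) and PLBL (N m) of the
densely resampled solution, normalized ratios against the human-only
tracking block, phase durations and solver diagnostics.  All of it is
recomputable from the stored trajectory files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import build_from_config
from .ocp import OCPSolution, OCPSpec, build_ocp, initial_guess_from_reference, solve_ocp
from .risk import clbl_analysis, plbl_analysis
from .synthetic import LiftScenario, ReferenceMotion
from .trajectory import Trajectory

log = logging.getLogger(__name__)

VARIANTS = ("HO", "HwE")
COSTS = ("LSQ", "CLBL", "PLBL", "HYB")


@dataclass
class BlockResult:
    variant: str
    cost: str
    solution: OCPSolution | None
    trajectory: Trajectory | None
    clbl: float = np.nan
    plbl: float = np.nan
    durations: np.ndarray | None = None
    objective: float = np.nan
    n_iter: int = -1
    success: bool = False
    message: str = ""

    @property
    def name(self) -> str:
        return f"{self.variant}-{self.cost}"


@dataclass
class StudyResult:
    """All eight blocks plus the reference motion they share."""

    blocks: dict[str, BlockResult]
    reference: Trajectory
    config: dict
    seed: int

    def table(self) -> pd.DataFrame:
        """Per-block CLBL/PLBL with ratios against the HO tracking block."""
        base = self.blocks.get("HO-LSQ")
        rows = []
        for b in self.blocks.values():
            if b.trajectory is None:
                continue
            rows.append(
                dict(
                    block=b.name,
                    variant=b.variant,
                    cost=b.cost,
                    clbl_Nms=b.clbl,
                    plbl_Nm=b.plbl,
                    clbl_ratio=b.clbl / base.clbl if base else np.nan,
                    plbl_ratio=b.plbl / base.plbl if base else np.nan,
                    T1_s=b.durations[0],
                    T2_s=b.durations[1],
                    T3_s=b.durations[2],
                    total_s=float(np.sum(b.durations)),
                    objective=b.objective,
                    iterations=b.n_iter,
                    converged=b.success,
                )
            )
        return pd.DataFrame(rows)

    def durations_table(self) -> pd.DataFrame:
        df = self.table()
        return df[["block", "T1_s", "T2_s", "T3_s", "total_s"]]


def _analyze(traj: Trajectory) -> tuple[float, float]:
    m = traj.extras["l5s1_moment"]
    return clbl_analysis(traj.time, m), plbl_analysis(m)


def _solve_block(lm, spec, motion, guesses, candidates=()) -> BlockResult:
    ocp = build_ocp(lm, spec, motion)
    cand = [c(ocp) for c in candidates]
    cand = [c for c in cand if c is not None]
    best = None
    for guess in guesses:
        x0 = guess(ocp)
        if x0 is None:
            continue
        sol = solve_ocp(ocp, x0, candidates=tuple(cand))
        if best is None or (sol.success and sol.objective < best.objective):
            if sol.success or best is None:
                best = sol
    b = BlockResult(variant=spec.variant, cost=spec.cost.kind, solution=best,
                    trajectory=None)
    if best is not None:
        b.objective = best.objective
        b.n_iter = best.n_iter
        b.success = best.success
        b.message = best.message
        if best.success:
            traj = best.trajectory()
            b.trajectory = traj
            b.clbl, b.plbl = _analyze(traj)
            b.durations = best.durations
    return b


def run_study(cfg: dict, seed: int | None = None) -> StudyResult:
    """Generate the synthetic reference and solve all eight blocks.

    A failed block is reported with its failure message; the remaining
    blocks still run (partial report).
    """
    scenario = LiftScenario.from_config(cfg)
    if seed is not None:
        scenario.seed = int(seed)
    blocks: dict[str, BlockResult] = {}
    ho_solutions: dict[str, OCPSolution] = {}
    reference_traj = None

    def _from_sol(sol):
        return lambda o, s=sol: initial_guess_from_reference(o, from_solution=s)

    for variant in VARIANTS:
        lm = build_from_config(cfg, with_exo=(variant == "HwE"))
        motion = ReferenceMotion(lm, scenario)
        if reference_traj is None:
            reference_traj = motion.sample()
        log.info("solving %s tracking block", variant)
        lsq_spec = OCPSpec.from_config(cfg, variant, "LSQ", motion.durations)
        lsq_block = _solve_block(
            lm, lsq_spec, motion, [lambda o: initial_guess_from_reference(o)]
        )
        blocks[lsq_block.name] = lsq_block
        lsq_sol = lsq_block.solution
        variant_solutions: dict[str, OCPSolution] = {}
        for kind in ("CLBL", "PLBL", "HYB"):
            log.info("solving %s %s block", variant, kind)
            spec = OCPSpec.from_config(cfg, variant, kind, motion.durations)
            if lsq_sol is not None and lsq_sol.success:
                lsq_guess = _from_sol(lsq_sol)
            else:
                lsq_guess = lambda o: initial_guess_from_reference(o)
            if variant == "HwE" and kind in ho_solutions:
                # warm-start from the matching human-only technique; the
                # tracking solution stays registered as a fallback bound
                guesses = [lambda o, s=ho_solutions[kind]: _map_ho_guess(o, s)]
                candidates = [lsq_guess]
            else:
                guesses = [lsq_guess]
                candidates = []
            if kind == "HYB":
                # the hybrid objective is the sum of the other two, so their
                # solved techniques are natural deterministic multistarts
                for sib in ("PLBL", "CLBL"):
                    if sib in variant_solutions:
                        guesses.append(_from_sol(variant_solutions[sib]))
            else:
                # siblings already solved enter as feasible candidates only
                candidates += [_from_sol(s) for s in variant_solutions.values()]
            block = _solve_block(lm, spec, motion, guesses, candidates)
            blocks[block.name] = block
            if block.solution is not None and block.success:
                variant_solutions[kind] = block.solution
        # cross-candidate pass: a block adopts a sibling's technique when it
        # is feasible and strictly better under the block's own objective
        _cross_candidates(blocks, variant, variant_solutions)
        if variant == "HO":
            for kind in ("CLBL", "PLBL", "HYB"):
                b = blocks[f"HO-{kind}"]
                if b.solution is not None and b.success:
                    ho_solutions[kind] = b.solution
    return StudyResult(blocks=blocks, reference=reference_traj,
                       config=cfg, seed=scenario.seed)


def _cross_candidates(blocks, variant, variant_solutions) -> None:
    from .ocp import FEAS_TOL, OCPSolution

    for kind in ("CLBL", "PLBL", "HYB"):
        b = blocks.get(f"{variant}-{kind}")
        if b is None or b.solution is None or not b.success:
            continue
        ocp = b.solution.ocp
        for sib_kind, sib in variant_solutions.items():
            if sib_kind == kind:
                continue
            x = initial_guess_from_reference(ocp, from_solution=sib)
            J = ocp.objective(x)
            if ocp.max_violation(x) <= FEAS_TOL and J < b.objective - 1e-12:
                log.info(
                    "%s-%s adopts the %s technique (%.6g < %.6g)",
                    variant, kind, sib_kind, J, b.objective,
                )
                b.solution = OCPSolution(
                    spec=b.solution.spec, x=np.asarray(x, float), objective=float(J),
                    success=True, message=f"adopted {sib_kind} technique",
                    n_iter=b.n_iter, max_violation=float(ocp.max_violation(x)),
                    ocp=ocp,
                )
                b.objective = float(J)
                traj = b.solution.trajectory()
                b.trajectory = traj
                b.clbl, b.plbl = _analyze(traj)
                b.durations = b.solution.durations
                b.message = b.solution.message


def _map_ho_guess(ocp, ho_solution: OCPSolution) -> np.ndarray | None:
    """Map a human-only predictive solution onto the exoskeleton problem."""
    src = ho_solution.ocp.unpack(ho_solution.x)
    if len(src["zeta"]) != ocp.K:
        return None
    u = np.zeros(ocp.K)
    return ocp.pack(src["zeta"], src["w"], u, src["durations"])


# -- reporting ----------------------------------------------------------


def render_reports(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    """Write CSV tables, trajectory files and summary figures.

    Returns the paths written.  Raises on an empty result.
    """
    solved = [b for b in result.blocks.values() if b.trajectory is not None]
    if not solved:
        raise ValueError("no solved blocks to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = result.table()
    paths["risk_table"] = outdir / "risk_metrics.csv"
    table.to_csv(paths["risk_table"], index=False, float_format="%.6g")
    paths["durations"] = outdir / "phase_durations.csv"
    result.durations_table().to_csv(paths["durations"], index=False,
                                    float_format="%.6g")
    for b in solved:
        p = outdir / f"trajectory_{b.name}.csv"
        b.trajectory.to_csv(p)
        paths[f"trajectory_{b.name}"] = p
    paths["reference"] = outdir / "trajectory_reference.csv"
    result.reference.to_csv(paths["reference"])
    paths["manifest"] = outdir / "run_manifest.json"
    manifest = dict(
        seed=result.seed,
        blocks={
            b.name: dict(converged=bool(b.success), iterations=int(b.n_iter),
                         objective=float(b.objective), message=b.message)
            for b in result.blocks.values()
        },
    )
    paths["manifest"].write_text(json.dumps(manifest, indent=2))

    paths.update(_figures(result, outdir))
    return paths


def _figures(result: StudyResult, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    base = result.blocks.get("HO-LSQ")
    table = result.table()

    # normalized bar chart (CLBL and PLBL ratios per block)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col, label in zip(
        axes, ("clbl_ratio", "plbl_ratio"), ("CLBL (normalized)", "PLBL (normalized)")
    ):
        for variant, shade in (("HO", "0.55"), ("HwE", "white")):
            sub = table[table.variant == variant]
            xs = np.arange(len(sub)) + (0.0 if variant == "HO" else 0.4)
            ax.bar(xs, sub[col], width=0.38, color=shade, edgecolor="k",
                   label=variant)
            for x, v in zip(xs, sub[col]):
                ax.text(x, v + 0.02, f"{v:.2f}", ha="center", fontsize=7)
        ax.set_xticks(np.arange(4) + 0.2)
        ax.set_xticklabels(sub.cost)
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
    fig.tight_layout()
    paths["fig_bars"] = outdir / "normalized_loads.png"
    fig.savefig(paths["fig_bars"], dpi=150)
    plt.close(fig)

    # L5/S1 moment and lumbar flexion time series with phase shading
    for key, ylabel, fname in (
        ("l5s1_moment", "L5/S1 extension moment (N m)", "l5s1_moment.png"),
        ("lumbar_flexion_deg", "lumbar flexion (deg)", "lumbar_flexion.png"),
    ):
        fig, axes = plt.subplots(1, 2, figsize=(10, 3.5), sharey=True)
        for ax, variant in zip(axes, ("HO", "HwE")):
            for b in result.blocks.values():
                if b.variant != variant or b.trajectory is None:
                    continue
                t = b.trajectory.time / b.trajectory.time[-1]
                ax.plot(t, b.trajectory.extras[key], label=b.cost, lw=1.2)
            if base is not None and base.trajectory is not None:
                bounds = np.cumsum(np.concatenate([[0.0], base.durations]))
                for x0, x1, c in zip(bounds[:-1] / bounds[-1], bounds[1:] / bounds[-1],
                                     ("0.92", "0.85", "0.92")):
                    ax.axvspan(x0, x1, color=c, zorder=0)
            ax.set_title(variant)
            ax.set_xlabel("normalized time")
            ax.legend(fontsize=8)
        axes[0].set_ylabel(ylabel)
        fig.tight_layout()
        paths[f"fig_{key}"] = outdir / fname
        fig.savefig(paths[f"fig_{key}"], dpi=150)
        plt.close(fig)
    return paths
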