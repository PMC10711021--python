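"""Iterative particle sieving by highpass-band energy scores.

A particle image b is scored against the forward projection p = A x of the
current reference map by

    g = ||H b||^2 - ||H (b - p)||^2 = 2 <H b, H p> - ||H p||^2

where H is a sharp highpass projector at the iteration's cutoff frequency.
The score measures the highpass-band signal energy the particle shares with
its reference projection: particles with wrong poses, wrong CTFs or strong
high-frequency damage share little band energy and score low. Each
iteration scores every retained particle against its *own half-set* map
(scores are never pooled across half-sets), removes the bottom fraction,
and rebuilds the half-maps from the survivors, so the retained index sets
are nested across iterations by construction. The cutoff frequency rises
linearly in frequency (not in resolution) from the starting to the final
cutoff over the scheduled iterations.

A normalized cross-correlation (NCC) scorer is provided as the standard
comparator; it ranks by the Pearson correlation of pixel intensities and
carries no band selection or amplitude sensitivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .formats import ParticleStack, VoxelGrid, write_mrc, write_star
from .geometry import FourierProjector, forward_project
from .reconstruct import (
    MaskSpec,
    fsc,
    make_mask,
    reconstruct,
    resolution_at_threshold,
)

__all__ = [
    "SieveSchedule",
    "SieveState",
    "SieveResult",
    "cutoff_schedule",
    "highpass",
    "cryosieve_score",
    "ncc_score",
    "sieve_iteration",
    "run_sieve",
]

logger = logging.getLogger("particlesieve")


@dataclass
class SieveSchedule:
    """Iteration count, per-iteration retention and cutoff ramp endpoints."""

    n_iterations: int = 9
    retention: float = 0.8
    cutoff_start_A: float = 40.0
    cutoff_final_A: float = 3.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.retention < 1.0:
            raise ValueError("retention must be in (0, 1)")
        if not self.cutoff_start_A > self.cutoff_final_A > 0:
            raise ValueError("need cutoff_start_A > cutoff_final_A > 0")


@dataclass
class SieveState:
    """Snapshot after iteration k: nested retained sets, scores and maps."""

    k: int
    cutoff_A: float
    retained: Dict[int, np.ndarray]  # half-set -> sorted original indices
    scores: Dict[int, np.ndarray]  # half-set -> score per retained index
    maps: Dict[int, VoxelGrid] = field(default_factory=dict)
    resolution_A: Optional[float] = None

    @property
    def n_retained(self) -> Dict[int, int]:
        return {h: len(v) for h, v in self.retained.items()}


@dataclass
class SieveResult:
    states: List[SieveState]
    report: pd.DataFrame
    halted: bool = False
    halt_reason: str = ""

    def suggest_finest(self, tolerance_A: float = 0.05) -> int:
        """Heuristic finest-subset suggestion: the last iteration whose FSC
        resolution is within ``tolerance_A`` Angstrom of the best. The
        choice is advisory; inspect the full report before adopting it."""
        res = [s.resolution_A for s in self.states if s.resolution_A is not None]
        if not res:
            return len(self.states)
        best = min(res)
        k = 0
        for s in self.states:
            if s.resolution_A is not None and s.resolution_A <= best + tolerance_A:
                k = s.k
        return k


def cutoff_schedule(k: int, schedule: SieveSchedule) -> float:
    """Highpass cutoff (Angstrom) at iteration k, linear in frequency."""
    n = schedule.n_iterations
    if not 1 <= k <= n:
        raise ValueError(f"iteration {k} outside 1..{n}")
    f_start = 1.0 / schedule.cutoff_start_A
    f_final = 1.0 / schedule.cutoff_final_A
    if n == 1:
        return schedule.cutoff_final_A
    f = f_start + (k - 1) / (n - 1) * (f_final - f_start)
    return 1.0 / f


def _highpass_mask(L: int, cutoff_A: float, pixel_size: float) -> np.ndarray:
    nyquist = 1.0 / (2.0 * pixel_size)
    if 1.0 / cutoff_A > nyquist:
        raise ValueError(
            f"cutoff {cutoff_A} A is beyond Nyquist ({1.0 / nyquist:.3g} A)"
        )
    f = np.fft.fftfreq(L, d=pixel_size)
    r = np.hypot(f[None, :], f[:, None])
    return r >= 1.0 / cutoff_A


def highpass(image: np.ndarray, cutoff_A: float, pixel_size: float) -> np.ndarray:
    """Sharp radial highpass: zero all |f| < 1/cutoff_A, identity above.

    An orthogonal projector in Fourier space (idempotent, self-adjoint);
    the DC component is always removed.
    """
    L = image.shape[-1]
    mask = _highpass_mask(L, cutoff_A, pixel_size)
    return np.fft.ifft2(np.fft.fft2(image) * mask).real


def cryosieve_score(b: np.ndarray, proj: np.ndarray, cutoff_A: float,
                    pixel_size: float) -> float:
    """Sieving score g = ||H b||^2 - ||H (b - p)||^2 (real-space energies)."""
    if b.shape != proj.shape:
        raise ValueError(f"shape mismatch: {b.shape} vs {proj.shape}")
    hb = highpass(b, cutoff_A, pixel_size)
    hr = highpass(b - proj, cutoff_A, pixel_size)
    return float(np.sum(hb * hb) - np.sum(hr * hr))


def ncc_score(b: np.ndarray, proj: np.ndarray) -> float:
    """Pearson correlation of pixel intensities, in [-1, 1]."""
    if b.shape != proj.shape:
        raise ValueError(f"shape mismatch: {b.shape} vs {proj.shape}")
    bv = b - b.mean()
    pv = proj - proj.mean()
    denom = math.sqrt(float(np.sum(bv * bv)) * float(np.sum(pv * pv)))
    if denom == 0.0:
        raise ValueError("zero-variance input to ncc_score")
    return float(np.sum(bv * pv) / denom)


def _score_half_set(
    stack: ParticleStack,
    indices: np.ndarray,
    reference: VoxelGrid,
    cutoff_A: float,
    scorer: str,
) -> np.ndarray:
    """Score the given record positions against one half-set reference map."""
    projector = FourierProjector(reference)
    px = stack.pixel_size
    scores = np.empty(len(indices))
    for j, i in enumerate(indices):
        r = stack.records[i]
        b = stack.images[i].astype(np.float64)
        p = forward_project(reference, r.pose, r.ctf, projector=projector)
        if scorer == "cryosieve":
            scores[j] = cryosieve_score(b, p, cutoff_A, px)
        elif scorer == "ncc":
            scores[j] = ncc_score(b, p)
        else:
            raise ValueError(f"unknown scorer {scorer!r}")
    return scores


def _retained_positions(stack: ParticleStack) -> Dict[int, np.ndarray]:
    halves: Dict[int, list] = {1: [], 2: []}
    for pos, r in enumerate(stack.records):
        halves[r.half_set].append(pos)
    return {h: np.asarray(v, dtype=np.int64) for h, v in halves.items() if v}


def sieve_iteration(
    stack: ParticleStack,
    state: SieveState,
    schedule: SieveSchedule,
    scorer: str = "cryosieve",
    mask_spec: MaskSpec = MaskSpec(),
    mask: Optional[VoxelGrid] = None,
    min_half_set: int = 16,
    recon_pad: int = 2,
) -> SieveState:
    """One sieving pass: mask each half-map, score that half-set's retained
    particles against it, keep the top floor(retention * n) (ties broken by
    ascending original index), and rebuild the half-maps from survivors."""
    k = state.k + 1
    cutoff = cutoff_schedule(k, schedule)
    new_retained: Dict[int, np.ndarray] = {}
    new_scores: Dict[int, np.ndarray] = {}
    for h, idx in state.retained.items():
        ref = state.maps[h]
        masked = _apply_mask(ref, mask, mask_spec)
        scores = _score_half_set(stack, idx, masked, cutoff, scorer)
        n_keep = int(math.floor(schedule.retention * len(idx)))
        if n_keep < min_half_set:
            raise SieveHalted(
                f"half-set {h} would shrink to {n_keep} < floor {min_half_set}"
            )
        # descending score, ties by ascending original index
        order = np.lexsort((idx, -scores))
        keep = np.sort(idx[order[:n_keep]])
        new_retained[h] = keep
        pos_of = {int(i): j for j, i in enumerate(idx)}
        new_scores[h] = scores[[pos_of[int(i)] for i in keep]]
    new_maps = {
        h: reconstruct(stack, [stack.records[i] for i in pos], pad=recon_pad)
        for h, pos in new_retained.items()
    }
    res = None
    if len(new_maps) == 2:
        curve = fsc(new_maps[1], new_maps[2])
        res = resolution_at_threshold(curve, 0.143).resolution_A
    return SieveState(k=k, cutoff_A=cutoff, retained=new_retained,
                      scores=new_scores, maps=new_maps, resolution_A=res)


class SieveHalted(RuntimeError):
    """Raised when a half-set would shrink below the configured floor."""


def _apply_mask(ref: VoxelGrid, mask: Optional[VoxelGrid],
                mask_spec: MaskSpec) -> VoxelGrid:
    if mask is None:
        mask = make_mask(ref, mask_spec)
    return VoxelGrid(data=ref.data * mask.data, voxel_size=ref.voxel_size)


def run_sieve(
    stack: ParticleStack,
    schedule: SieveSchedule = SieveSchedule(),
    initial_maps: Optional[Dict[int, VoxelGrid]] = None,
    mask: Optional[VoxelGrid] = None,
    mask_spec: MaskSpec = MaskSpec(),
    scorer: str = "cryosieve",
    min_half_set: int = 16,
    recon_pad: int = 2,
    outdir: Optional[Path] = None,
) -> SieveResult:
    """Run the full sieve: per-iteration score -> remove -> reconstruct.

    Initial half-maps are reconstructed from the full input stack (from the
    poses it carries) unless ``initial_maps`` provides them. Per-iteration
    STAR/MRC outputs are written under ``outdir`` when given. The retained
    sets are checked to be nested after every iteration.
    """
    halves = _retained_positions(stack)
    if initial_maps is None:
        initial_maps = {
            h: reconstruct(stack, [stack.records[i] for i in idx], pad=recon_pad)
            for h, idx in halves.items()
        }
    state = SieveState(k=0, cutoff_A=float("inf"), retained=halves,
                       scores={h: np.zeros(len(v)) for h, v in halves.items()},
                       maps=initial_maps)
    states: List[SieveState] = []
    rows = []
    halted, reason = False, ""
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    for k in range(1, schedule.n_iterations + 1):
        try:
            new_state = sieve_iteration(
                stack, state, schedule, scorer=scorer, mask_spec=mask_spec,
                mask=mask, min_half_set=min_half_set, recon_pad=recon_pad,
            )
        except SieveHalted as exc:
            halted, reason = True, str(exc)
            logger.warning("sieve halted at iteration %d: %s", k, reason)
            break
        for h in new_state.retained:
            if not set(map(int, new_state.retained[h])) <= set(
                map(int, state.retained[h])
            ):
                raise AssertionError(
                    f"retained set of half {h} not nested at iteration {k}"
                )
        state = new_state
        states.append(state)
        counts = state.n_retained
        row = {
            "iteration": k,
            "cutoff_A": round(state.cutoff_A, 4),
            "n_half1": counts.get(1, 0),
            "n_half2": counts.get(2, 0),
            "cumulative_pct": round(100.0 * schedule.retention**k, 1),
            "resolution_A": (round(state.resolution_A, 3)
                             if state.resolution_A is not None else float("nan")),
        }
        rows.append(row)
        logger.info(
            "iteration %d: cutoff %.2f A, retained %s, scheduled %.1f%%, "
            "FSC resolution %s",
            k, state.cutoff_A, counts, row["cumulative_pct"],
            row["resolution_A"],
        )
        if outdir is not None:
            _write_iteration(stack, state, outdir)
    report = pd.DataFrame(rows)
    if outdir is not None and not report.empty:
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    return SieveResult(states=states, report=report, halted=halted,
                       halt_reason=reason)


def _write_iteration(stack: ParticleStack, state: SieveState, outdir: Path) -> None:
    it_dir = outdir / f"iter_{state.k}"
    it_dir.mkdir(exist_ok=True)
    records = []
    for h, idx in state.retained.items():
        for score, i in zip(state.scores[h], idx):
            records.append(replace(stack.records[i], score=float(score)))
    records.sort(key=lambda r: r.image_index)
    write_star(records, it_dir / "retained.star")
    for h, vol in state.maps.items():
        write_mrc(vol, it_dir / f"half{h}.mrc")
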