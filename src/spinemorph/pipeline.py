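"""End-to-end pipeline: detect -> edit -> segment -> edit -> trace -> measure.

The pipeline is fully headless and reproducible: a configuration plus the
input stack, SWC trace and an optional edit script determine every output.
Edits are replayable text commands (the auditable analogue of interactive
clicking):

    add_seed X Y Z       add a manual seed near voxel (X, Y, Z)
    remove_seed X Y Z    delete the seed nearest voxel (X, Y, Z)
    merge A B            merge head label B into head label A
    remove_head L        delete head label L
    retrace L X Y Z      re-trace neck of head L from head-border voxel (X, Y, Z)

Command coordinates are 0-based voxel indices in X Y Z order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, necks, segmentation
from .detection import DetectionParams, Seed
from .image_io import ImageStack, read_stack, write_overlay, write_stack
from .measure import SpineRecord, summarize
from .measure import head_surface as _head_surface
from .measure import head_volume as _head_volume
from .necks import NeckPath
from .segmentation import SegmentationParams, SpineHead
from .swc import DendriteModel, DendriteVolume, parse_swc, rasterize_dendrite

logger = logging.getLogger(__name__)


class EditScriptError(ValueError):
    """Raised for a malformed edit command, naming the line."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    stack_path: str | Path | None = None
    swc_path: str | Path | None = None
    spacing_override: tuple[float, float, float] | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    neck_mode: str = "traced"  # traced | straight_line
    output_dir: str | Path = "results"
    edit_script: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neck_mode not in ("traced", "straight_line"):
            raise ValueError(f"unknown neck mode {self.neck_mode!r}")


@dataclass
class PipelineState:
    """Mutable state carried through the stages."""

    image: ImageStack
    model: DendriteModel
    volume: DendriteVolume
    config: RunConfig
    seeds: list[Seed] = field(default_factory=list)
    heads: list[SpineHead] = field(default_factory=list)
    label_grid: np.ndarray | None = None
    neck_paths: dict[int, NeckPath] = field(default_factory=dict)
    records: list[SpineRecord] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.log.append(msg)
        logger.info(msg)


def build_state(
    image: ImageStack, model: DendriteModel, config: RunConfig | None = None
) -> PipelineState:
    """Rasterize the dendrite onto the image grid and initialize state."""
    config = config or RunConfig()
    volume = rasterize_dendrite(
        model, image.spacing, grid_shape=image.shape, origin=(0.0, 0.0, 0.0)
    )
    state = PipelineState(image=image, model=model, volume=volume, config=config)
    state.note(
        f"grid {image.shape} spacing {image.spacing} µm; "
        f"dendrite {int(volume.mask.sum())} voxels, length {model.length():.3f} µm"
    )
    return state


def detect_stage(state: PipelineState) -> PipelineState:
    state.seeds = detection.detect_local_maxima(
        state.image,
        state.volume.border_distance,
        state.config.detection,
        dendrite_mask=state.volume.mask,
    )
    state.note(f"detected {len(state.seeds)} seeds with {state.config.detection}")
    return state


def segment_stage(state: PipelineState) -> PipelineState:
    if not state.seeds:
        state.heads, state.label_grid = [], np.zeros(state.image.shape, np.int32)
        state.note("no seeds; empty segmentation")
        return state
    state.heads, state.label_grid = segmentation.segment_heads(
        state.image, state.seeds, state.volume, state.config.segmentation
    )
    state.note(f"segmented {len(state.heads)} heads with {state.config.segmentation}")
    return state


def trace_stage(state: PipelineState) -> PipelineState:
    """Classify stubby vs necked and trace (or estimate) every neck."""
    if state.config.neck_mode == "traced" and state.image.is_2d:
        raise ValueError("neck tracing requires a 3D stack; 2D images support "
                         "detection and segmentation only")
    state.neck_paths = {}
    for head in state.heads:
        hmask = head.mask(state.image.shape)
        kind = necks.classify_stubby(hmask, state.volume.mask)
        if kind == "stubby":
            continue
        if state.config.neck_mode == "straight_line":
            length = necks.straight_line_length(head, state.volume.mask, state.image.spacing)
            state.neck_paths[head.label] = NeckPath(
                voxels=[], length=length, mode="straight_line", label=head.label
            )
        else:
            hv, dv, _ = necks.closest_border_pair(
                hmask, state.volume.mask, state.image.spacing
            )
            state.neck_paths[head.label] = necks.trace_neck(
                state.image, hv, dv, hmask, state.volume.mask, label=head.label
            )
    state.note(
        f"traced {len(state.neck_paths)} necks (mode={state.config.neck_mode}); "
        f"{len(state.heads) - len(state.neck_paths)} stubby"
    )
    return state


def measure_stage(state: PipelineState) -> PipelineState:
    records = []
    for head in state.heads:
        hmask = head.mask(state.image.shape)
        kind = necks.classify_stubby(hmask, state.volume.mask)
        if kind == "stubby":
            neck_length = 0.0
            distance = 0.0
        else:
            _, _, distance = necks.closest_border_pair(
                hmask, state.volume.mask, state.image.spacing
            )
            path = state.neck_paths.get(head.label)
            neck_length = path.length if path is not None else distance
        cx, cy, cz = head.centroid
        records.append(
            SpineRecord(
                spine_id=head.label,
                head_volume=_head_volume(head, state.image.spacing),
                head_surface=_head_surface(head, state.image.spacing),
                neck_length=neck_length,
                spine_type=kind,
                head_centroid=(float(cx), float(cy), float(cz)),
                distance_to_dendrite=float(distance),
                edit_provenance=head.provenance,
            )
        )
    state.records = records
    state.note(f"measured {len(records)} spines")
    return state


# ---------------------------------------------------------------------------
# edit scripts

_SEED_COMMANDS = {"add_seed", "remove_seed"}
_HEAD_COMMANDS = {"merge", "remove_head"}
_NECK_COMMANDS = {"retrace"}


def parse_edit_script(text: str) -> list[tuple[str, list[int]]]:
    """Parse an edit script into (command, int-args) tuples; '#' comments."""
    commands: list[tuple[str, list[int]]] = []
    arity = {"add_seed": 3, "remove_seed": 3, "merge": 2, "remove_head": 1, "retrace": 4}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        cmd, args = parts[0], parts[1:]
        if cmd not in arity:
            raise EditScriptError(f"line {lineno}: unknown command {cmd!r}")
        if len(args) != arity[cmd]:
            raise EditScriptError(
                f"line {lineno}: {cmd} takes {arity[cmd]} arguments, got {len(args)}"
            )
        try:
            commands.append((cmd, [int(a) for a in args]))
        except ValueError as exc:
            raise EditScriptError(f"line {lineno}: {exc}") from exc
    return commands


def _xyz_to_voxel(x: int, y: int, z: int) -> tuple[int, int, int]:
    return (z, y, x)


def apply_edit_script(state: PipelineState, script: str) -> PipelineState:
    """Apply edit commands in order to the current state.

    Seed edits re-run segmentation and tracing when those stages had already
    produced output, so the state stays consistent; every edit is logged.
    """
    for cmd, args in parse_edit_script(script):
        apply_edit(state, cmd, args)
    return state


def apply_edit(state: PipelineState, cmd: str, args: list[int]) -> None:
    if cmd == "add_seed":
        seed = detection.add_seed_at(state.image, _xyz_to_voxel(*args))
        state.seeds = state.seeds + [seed]
        state.note(f"edit add_seed {args} -> seed at {seed.voxel}")
        _invalidate_downstream(state)
    elif cmd == "remove_seed":
        state.seeds, removed = detection.remove_nearest_seed(
            state.seeds, _xyz_to_voxel(*args), state.image.spacing
        )
        state.note(f"edit remove_seed {args} -> removed {removed.voxel}")
        _invalidate_downstream(state)
    elif cmd == "merge":
        a, b = args
        state.label_grid, state.heads = segmentation.merge_heads(
            state.label_grid, state.heads, a, b
        )
        state.neck_paths.pop(b, None)
        state.note(f"edit merge {b} into {a}")
    elif cmd == "remove_head":
        (label,) = args
        state.label_grid, state.heads = segmentation.remove_head(
            state.label_grid, state.heads, label
        )
        state.neck_paths.pop(label, None)
        state.note(f"edit remove_head {label}")
    elif cmd == "retrace":
        label, x, y, z = args
        head = next(h for h in state.heads if h.label == label)
        state.neck_paths[label] = necks.retrace_neck(
            state.image,
            head.mask(state.image.shape),
            _xyz_to_voxel(x, y, z),
            state.volume.mask,
            label=label,
        )
        state.note(f"edit retrace head {label} from {(x, y, z)}")
    else:  # pragma: no cover - parse_edit_script already rejects these
        raise EditScriptError(f"unknown command {cmd!r}")


def _invalidate_downstream(state: PipelineState) -> None:
    if state.label_grid is not None:
        segment_stage(state)
        if state.neck_paths:
            trace_stage(state)


# ---------------------------------------------------------------------------
# full run


def run_pipeline(
    config: RunConfig,
    image: ImageStack | None = None,
    model: DendriteModel | None = None,
) -> Path:
    """Run every stage and write all results to ``config.output_dir``.

    Inputs may be passed in memory or read from the configured paths.
    Edit commands are routed to their natural stage: seed edits after
    detection, head edits after segmentation, retraces after tracing.
    """
    if image is None:
        if config.stack_path is None:
            raise ValueError("no image: set stack_path or pass one in memory")
        image = read_stack(config.stack_path, config.spacing_override)
    if model is None:
        if config.swc_path is None:
            raise ValueError("no dendrite: set swc_path or pass a model in memory")
        model = parse_swc(Path(config.swc_path).read_text())

    commands: list[tuple[str, list[int]]] = []
    if config.edit_script is not None:
        commands = parse_edit_script(Path(config.edit_script).read_text())

    state = build_state(image, model, config)
    detect_stage(state)
    for cmd, args in commands:
        if cmd in _SEED_COMMANDS:
            apply_edit(state, cmd, args)
    segment_stage(state)
    for cmd, args in commands:
        if cmd in _HEAD_COMMANDS:
            apply_edit(state, cmd, args)
    trace_stage(state)
    for cmd, args in commands:
        if cmd in _NECK_COMMANDS:
            apply_edit(state, cmd, args)
    measure_stage(state)
    return write_results(state)


def write_results(state: PipelineState) -> Path:
    """Write seeds, label stack, necks, overlay, table, summary and log."""
    out = Path(state.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {"i": s.voxel[0], "j": s.voxel[1], "k": s.voxel[2],
             "intensity": s.intensity, "origin": s.origin}
            for s in state.seeds
        ]
    ).to_csv(out / "seeds.csv", index=False)

    label_grid = (
        state.label_grid
        if state.label_grid is not None
        else np.zeros(state.image.shape, np.int32)
    )
    write_stack(
        out / "head_labels.tif",
        ImageStack(label_grid.astype(np.uint16), state.image.spacing),
    )

    with open(out / "neck_paths.json", "w") as fh:
        json.dump(
            {
                str(lab): {
                    "mode": p.mode,
                    "length_um": p.length,
                    "voxels": [list(v) for v in p.voxels],
                }
                for lab, p in sorted(state.neck_paths.items())
            },
            fh,
            indent=1,
        )

    write_overlay(
        state.image,
        state.volume.mask,
        label_grid,
        list(state.neck_paths.values()),
        path=out / "overlay.tif",
    )

    summary, table = summarize(state.records, state.model.length()) \
        if state.model.length() > 0 else (None, None)
    if table is not None:
        table.to_csv(out / "spines.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(asdict(summary), fh, indent=1)

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(state.log) + "\n")
    return out
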