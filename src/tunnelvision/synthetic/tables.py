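"""Grouped magnitude tables with known effect structure.

Emulates the habitat x quadrant scene-statistics data: each habitat type
contributes several filmed scenes (locations), each scene is measured in
every visual-field quadrant, and repeated videos of a scene share a random
scene intercept.  Because the generating effects are known exactly, the
statistics layer can be validated for calibration and power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..specs import StatsDesign

__all__ = ["TableEffects", "simulate_metric_table"]


@dataclass(frozen=True)
class TableEffects:
    """True generating effects for :func:`simulate_metric_table`.

    ``habitat``, ``quadrant`` and ``interaction`` map level (or level-pair)
    names to additive effects; unnamed levels default to 0.  ``sd_scene``
    is the between-scene random-intercept standard deviation, ``sd_residual``
    the within-cell noise.
    """

    grand_mean: float = 0.0
    habitat: dict = field(default_factory=dict)
    quadrant: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    sd_scene: float = 0.0
    sd_residual: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_scene < 0 or self.sd_residual < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_metric_table(
    design: StatsDesign,
    effects: TableEffects,
    n_per_cell: int,
    seed: int = 0,
    n_scenes_per_habitat: int = 3,
) -> pd.DataFrame:
    """Draw a long-format magnitude table under a known mixed-effects model.

    Each observation is
    ``grand_mean + habitat + quadrant + interaction + scene_intercept + noise``
    with ``n_per_cell`` observations per scene x quadrant cell.  Scenes are
    nested within habitats (3 per habitat by default, as in a three-location
    field survey).

    Returns a DataFrame with columns ``magnitude, habitat, quadrant, scene``.
    """
    if n_per_cell < 2:
        raise ValueError("need n >= 2 observations per cell")
    if n_scenes_per_habitat < 1:
        raise ValueError("need at least one scene per habitat")
    rng = np.random.default_rng(seed)
    rows = []
    for hab in design.habitats:
        for s in range(n_scenes_per_habitat):
            scene_id = f"{hab}_scene{s}"
            intercept = rng.normal(0.0, effects.sd_scene) if effects.sd_scene else 0.0
            for quad in design.quadrants:
                mu = (
                    effects.grand_mean
                    + effects.habitat.get(hab, 0.0)
                    + effects.quadrant.get(quad, 0.0)
                    + effects.interaction.get((hab, quad), 0.0)
                    + intercept
                )
                vals = mu + rng.normal(0.0, effects.sd_residual, n_per_cell)
                for v in vals:
                    rows.append((v, hab, quad, scene_id))
    return pd.DataFrame(rows, columns=["magnitude", "habitat", "quadrant", "scene"])
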