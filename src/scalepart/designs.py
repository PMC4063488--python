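"""Packaged study designs for the two headline simulation experiments.

Both designs analyze three doubling scales starting at a 4 km² grain
(2×2-pixel cells), where coarse cells mix LULC classes and the
variability→impact channel is active.

``recovery_study``: a community structured by climate alone on a 384 km
landscape (61 qualifying grids over 3 scales).  Correct attribution means
the climate exclusive fraction beats the LULC exclusive fraction grid by
grid, although the LULC constraint set is larger.

``experiment_design``: the affinity-vs-variability experiment.  The LULC
patch-diameter ladder 2–8 px moves the focal group's within-grid CV while
every patch stays well below the 64–128 px grid windows (beyond that, grids
degenerate toward single-patch coverage and the CV ladder itself folds
back).  Niche tolerance is widened to 0.5× the realized range so that
within-grid climate responses are near-linear: under the zero-affinity null
the linear climate conditioning is then complete, and the focal group's
exclusive fraction measures nothing but its own effect.  (The focal LULC
signal itself is carried by the categorical class preference, which the
continuous tolerance does not touch.)
"""

from __future__ import annotations

from .synthetic_data import LandscapeConfig

#: Patch-diameter ladder (pixels) generating the increasing CV series.
EXPERIMENT_PATCH_LADDER = [2.0, 3.0, 4.0, 6.0, 8.0]


def recovery_study_kwargs() -> dict:
    """Arguments to :func:`scalepart.pipeline.run_study` for the
    climate-affinity parameter-recovery study."""
    return dict(
        config=LandscapeConfig(width_px=384, height_px=384),
        group_affinity={"climate": 1.0, "lulc": 0.0},
        base_grain=4.0,
        n_scales=3,
        n_target=150_000,
        n_species=24,
    )


def experiment_kwargs() -> dict:
    """Shared arguments to :func:`scalepart.scaling_analysis.run_affinity_experiment`
    (both the positive arm and the zero-affinity control)."""
    return dict(
        base_config=LandscapeConfig(),
        cv_levels=list(EXPERIMENT_PATCH_LADDER),
        focal_group="lulc",
        base_grain=4.0,
        n_scales=3,
        n_target=60_000,
        tolerance_fraction=0.5,
    )
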