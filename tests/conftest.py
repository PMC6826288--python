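"""Shared fixtures: small analytic wings and cached synthetic tessellations."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import wingmorph as wm


@pytest.fixture()
def square_diag_wing() -> wm.SegmentedWing:
    """Unit square split by one diagonal: 4 vertices, 5 edges, 2 domains."""
    v = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    return wm.SegmentedWing(
        v, np.array([0, 1, 2, 3]),
        [np.array([0, 1, 2]), np.array([0, 2, 3])])


@pytest.fixture()
def circle_wing() -> wm.SegmentedWing:
    """Single-domain wing bounded by a fine polygonal circle."""
    t = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
    ring = np.column_stack([np.cos(t), np.sin(t)])
    return wm.SegmentedWing.from_domain_polygons([ring])


@pytest.fixture(scope="session")
def battery_wings() -> list[tuple[wm.SynthSpec, wm.SegmentedWing]]:
    """The canonical fixture battery, generated once per session."""
    return [(spec, wm.generate_synthetic_wing(spec))
            for spec in wm.fixture_battery()]


def match_fractional_areas(
    generated: wm.SegmentedWing,
    segmented: wm.SegmentedWing,
    transform: tuple,
) -> np.ndarray:
    """Relative fractional-area error of each segmented domain against the
    generated domain containing its representative point."""
    scale, (ox, oy), _ = transform
    gen_polys = [Polygon(d.ring) for d in generated.domains]
    gen_fa = np.array([p.area for p in gen_polys])
    gen_fa /= gen_fa.sum()
    seg_fa = np.array([d.area for d in segmented.domains])
    seg_fa /= seg_fa.sum()
    errors = []
    for d, fa in zip(segmented.domains, seg_fa):
        c = Polygon(d.ring).representative_point()
        pt = Point((c.x - ox) / scale, (c.y - oy) / scale)
        hits = [j for j, p in enumerate(gen_polys) if p.contains(pt)]
        assert len(hits) == 1, "segmented domain centre not inside a unique source domain"
        errors.append(abs(fa - gen_fa[hits[0]]) / gen_fa[hits[0]])
    return np.asarray(errors)
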