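import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from reefscore import (  # noqa: E402
    ARUnitDesign,
    FactorSet,
    NestCavity,
    ThroughHole,
    galician_unit,
    reference_cube,
)


@pytest.fixture(scope="session")
def reference():
    return reference_cube()


@pytest.fixture(scope="session")
def galician():
    return galician_unit()


@pytest.fixture(scope="session")
def galician_geometry_only():
    return galician_unit(use_table_overrides=False)


@pytest.fixture
def bare_cube():
    return ARUnitDesign(name="bare", length=1.0, width=1.0, height=1.0)


@pytest.fixture
def default_factors():
    return FactorSet()


def make_cube(name="cube", edge=1.5, cavities=(), holes=()):
    """Convenience constructor used across test modules."""
    return ARUnitDesign(
        name=name,
        length=edge,
        width=edge,
        height=edge,
        nest_cavities=list(cavities),
        through_holes=list(holes),
    )


def lateral_hole(diameter, face="north", connects="opposite_face", center=(0.0, 0.0)):
    return ThroughHole(
        diameter=diameter,
        orientation="horizontal_lateral",
        host_face=face,
        connects_to=connects,
        center=center,
    )


def scale_design(design, c):
    """Uniformly scale every linear dimension of a design by ``c``."""
    return design.model_copy(
        update={
            "length": design.length * c,
            "width": design.width * c,
            "height": design.height * c,
            "slab_height": design.slab_height * c,
            "through_holes": [
                h.model_copy(
                    update={
                        "diameter": h.diameter * c,
                        "depth": None if h.depth is None else h.depth * c,
                        "center": (h.center[0] * c, h.center[1] * c),
                    }
                )
                for h in design.through_holes
            ],
            "nest_cavities": [
                n.model_copy(
                    update={
                        "diameter": n.diameter * c,
                        "depth": n.depth * c,
                        "center": (n.center[0] * c, n.center[1] * c),
                    }
                )
                for n in design.nest_cavities
            ],
        }
    )


def cavity(diameter, face="north", center=(0.0, 0.0), depth=None):
    return NestCavity(
        diameter=diameter,
        depth=depth if depth is not None else diameter,
        host_face=face,
        center=center,
    )
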