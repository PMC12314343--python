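import numpy as np
import pytest

from rsnmap.io_tables import SegmentedObject
from rsnmap.synthetic import SectionConfig, generate_section


@pytest.fixture(scope="session")
def small_config() -> SectionConfig:
    """Geometrically shrunk default world: same densities, ~1/16 the area."""
    return SectionConfig().scaled(0.25)


@pytest.fixture(scope="session")
def small_section(small_config):
    """One shrunk default-world section with probes, plus its ground truth."""
    return generate_section(small_config, seed=42)


def random_objects(rng: np.random.Generator, n: int, object_class: str = "cDC1"):
    """n random segmented objects with volumes, intensities and labels."""
    objs = []
    for i in range(n):
        objs.append(
            SegmentedObject(
                id=i,
                object_class=object_class,
                x=float(rng.uniform(0, 1000)),
                y=float(rng.uniform(0, 1000)),
                z=float(rng.uniform(0, 30)) if rng.uniform() < 0.5 else None,
                volume=float(rng.gamma(9, 20)),
                intensities={"ch1": float(rng.uniform(0, 5000))},
                labels={"state": rng.choice(["Cxcl9", "Il12b", "none"])},
            )
        )
    return objs
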