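"""Shared fixtures: deterministic templates and small planted assemblies."""

import numpy as np
import pytest

from trimkit import core_io, synthetic


@pytest.fixture(scope="session")
def ltr_template() -> str:
    return synthetic.make_ltr_template(np.random.default_rng(42), length=160)


@pytest.fixture(scope="session")
def internal_template() -> str:
    return synthetic.make_internal_template(np.random.default_rng(43), length=300)


@pytest.fixture(scope="session")
def small_planted(ltr_template, internal_template):
    """Two 30-kb scaffolds with one planted copy of each category."""
    assembly, _ = synthetic.generate_background(2, 30_000, gc=0.37, seed=4)
    specs = [
        synthetic.PlantSpec(ltr_template, internal_template,
                            core_io.GenomicInterval("scaffold_1", 5000, 5001),
                            age_years=2e6),
        synthetic.PlantSpec(ltr_template, internal_template,
                            core_io.GenomicInterval("scaffold_1", 15000, 15001),
                            category="solo_ltr", age_years=1e6),
        synthetic.PlantSpec(ltr_template, internal_template,
                            core_io.GenomicInterval("scaffold_2", 9000, 9001),
                            category="truncated", age_years=1e6,
                            truncation_fraction=0.6, truncation_side="5p"),
    ]
    planted, registry = synthetic.plant_elements(assembly, specs, seed=5)
    return planted, registry
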