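"""Shared fixtures: a miRBase-style worked-example catalog and simulators.

hsa-miR-9-5p's mature sequence is the canonical one; the miR-548k /
miR-548av-5p pair below is a SYNTHETIC stand-in (arbitrary sequences)
constructed to carry the documented conversion relation: trimming TCGT
off the 3' end of miR-548k yields exactly miR-548av-5p.
"""

import pytest

from isomir.io import MatureMiRNA, MiRNACatalog
from isomir.simulate import SimulationProfile, simulate_library, simulate_reference

MIR9_SEQ = "TCTTTGGTTATCTAGCTGTATGA"
MIR9_TRIM5_READ = "CTTTGGTTATCTAGCTGTATGA"

# synthetic stand-in pair: 548k = 548av-5p + 3' "TCGT"
MIR548AV_SEQ = "ACGGTTCAAGTACCTGAT"
MIR548K_SEQ = MIR548AV_SEQ + "TCGT"


@pytest.fixture
def worked_example_catalog() -> MiRNACatalog:
    return MiRNACatalog(
        [
            MatureMiRNA("hsa-miR-9-5p", MIR9_SEQ),
            MatureMiRNA("hsa-miR-548k", MIR548K_SEQ),
            MatureMiRNA("hsa-miR-548av-5p", MIR548AV_SEQ),
        ]
    )


@pytest.fixture
def default_simulation():
    """Reference + library under the default planted-modification profile."""
    profile = SimulationProfile(seed=42)
    reference, catalog = simulate_reference(profile)
    reads, aligned, truth = simulate_library(profile, reference, catalog)
    return profile, reference, catalog, reads, aligned, truth
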