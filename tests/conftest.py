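import numpy as np
import pytest

from raquant.rg4 import G4Motif, RG4Profile


def stub_profiles(n_positive, n_negative, region_plan=None):
    """Profiles with stub motifs: region_plan maps region -> motif count,
    distributed round-robin over the positive genes."""
    profiles = []
    motif_pool = []
    if region_plan:
        for region, count in region_plan.items():
            motif_pool += [region] * count
    per_gene = [[] for _ in range(n_positive)]
    for i, region in enumerate(motif_pool):
        per_gene[i % n_positive].append(region)
    for g in range(n_positive):
        regions = per_gene[g] or ["3UTR"]
        motifs = [
            G4Motif(start=0, end=20, tract_lengths=[3] * 4, loop_lengths=[1, 1, 1],
                    layers=3, representative_loop=1, score=0.9, region=r)
            for r in regions
        ]
        counts = {"5UTR": 0, "CDS": 0, "3UTR": 0}
        for r in regions:
            counts[r] += 1
        profiles.append(RG4Profile(f"POS{g:04d}", motifs, len(motifs), counts, True))
    for g in range(n_negative):
        profiles.append(
            RG4Profile(f"NEG{g:04d}", [], 0, {"5UTR": 0, "CDS": 0, "3UTR": 0}, False)
        )
    return profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
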