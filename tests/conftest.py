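import numpy as np
import pytest

from ecmevolve.barcodes import BarcodeCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_count_table():
    """Hand-built count table exercising every lineage-retention rule.

    Totals are 100,000 reads per sample so frequencies read off directly:
    200 reads = 0.2%, 50 = 0.05%, 600 = 0.6%, 10 = 0.01%.
    """
    lineages = {
        # barcode                 anc  s1   s2   s3   t1   t2   t3
        "AAAAAAAAAAAAAAAAAAAA": [200,   0,   0,   0,   0,   0,   0],  # rule 1
        "CCCCCCCCCCCCCCCCCCCC": [  0,  10,   0,   0,  10,   0,   0],  # rule 2 (cross-group)
        "GGGGGGGGGGGGGGGGGGGG": [  0,  50,   0,   0,   0,   0,   0],  # fails all
        "TTTTTTTTTTTTTTTTTTTT": [  0,  10,  10,  10,   0,   0,   0],  # rule 2 (>2 single group)
        "ACACACACACACACACACAC": [  0,   0,   0,   0,   0, 600,   0],  # rule 3
    }
    samples = ["anc", "soft1", "soft2", "soft3", "stiff1", "stiff2", "stiff3"]
    filler = [100_000 - sum(v[j] for v in lineages.values())
              for j in range(len(samples))]
    lineages["AGAGAGAGAGAGAGAGAGAG"] = filler  # dominant clone, rules 1+2+3
    per_sample = {s: {bc: v[j] for bc, v in lineages.items() if v[j] > 0}
                  for j, s in enumerate(samples)}
    groups = {"anc": "ancestral", "soft1": "soft", "soft2": "soft",
              "soft3": "soft", "stiff1": "stiff", "stiff2": "stiff",
              "stiff3": "stiff"}
    return BarcodeCountTable.from_sample_counts(per_sample, groups)
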