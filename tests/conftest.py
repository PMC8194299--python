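import numpy as np
import pytest

from epiblock import (FpkmPair, HomologyMap, MethylationDataset,
                      PreprocessConfig)


@pytest.fixture
def small_pair() -> FpkmPair:
    ip = np.array([[10.0, 2.0], [0.0, 30.0], [5.0, 5.0]])
    inp = np.array([[10.0, 8.0], [0.0, 10.0], [15.0, 5.0]])
    return FpkmPair(ip, inp, ("s1", "s2", "s3"), ("c1", "c2"))


@pytest.fixture
def write_tables(tmp_path):
    """Write a DataFrame-like dict of rows as a TSV matrix file."""

    def _write(name, values, site_ids, condition_ids, sep="\t"):
        path = tmp_path / name
        header = sep.join(["id", *condition_ids])
        lines = [header] + [
            sep.join([sid, *(str(v) for v in row)])
            for sid, row in zip(site_ids, values)
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def tiny_dataset() -> MethylationDataset:
    """8 sites x 6 conditions with a clear 3x2 hyper-methylated block."""
    rng = np.random.default_rng(11)
    p = np.clip(rng.normal(0.2, 0.03, (8, 6)), 0, 1)
    p[:3, :2] = 0.9
    w = rng.uniform(0.4, 0.6, (8, 6))
    sids = tuple(f"s{i}" for i in range(8))
    cids = tuple(f"c{j}" for j in range(6))
    return MethylationDataset(p, w, sids, cids,
                              HomologyMap.singleton(sids, cids))
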