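import json
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles


@pytest.fixture
def labelme_writer(tmp_path):
    """Write a LabelMe-dialect annotation file and return its path."""

    def write(shapes, height=16, width=16, name="ann.json"):
        payload = {
            "imageHeight": height,
            "imageWidth": width,
            "shapes": [{"label": lbl, "points": [[float(x), float(y)] for x, y in pts]}
                       for lbl, pts in shapes],
        }
        path = tmp_path / name
        path.write_text(json.dumps(payload))
        return path

    return write


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
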