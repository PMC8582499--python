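import numpy as np
import pytest

from tetrameth.bisulfite import MethylationMatrix


@pytest.fixture
def make_matrix():
    """Factory for small methylation matrices; rows as lists with None for
    non-informative sites."""

    def _make(clone_id, rows, conversion_ok=None):
        states = np.array(
            [[np.nan if v is None else float(v) for v in r] for r in rows]
        )
        return MethylationMatrix(
            clone_id=clone_id, states=states, conversion_ok=conversion_ok
        )

    return _make
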