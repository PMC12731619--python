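import numpy as np
import pytest

from flyquant import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_scene():
    """Two-channel noise-free scene with engineered 50% overlap."""
    spec = syn.SceneSpec(
        shape=(96, 96),
        channels=(
            syn.ChannelSpec("a", 5, 3, 4),
            syn.ChannelSpec("b", 5, 3, 4),
        ),
        overlap=syn.OverlapSpec(0, 1, fraction=0.5),
        seed=7,
    )
    return syn.generate_scene(spec)


def flood_fill_labels(binary, connectivity):
    """Brute-force BFS flood fill oracle; returns list of frozenset pixel sets."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    rows, cols = binary.shape
    for r in range(rows):
        for c in range(cols):
            if binary[r, c] and not seen[r, c]:
                comp = []
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                components.append(frozenset(comp))
    return components


def labelmap_partition(objmap):
    """Pixel-set partition of a LabeledObjectMap, for oracle comparison."""
    out = []
    for lab in range(1, objmap.n_objects + 1):
        rr, cc = np.nonzero(objmap.labels == lab)
        out.append(frozenset(zip(rr.tolist(), cc.tolist())))
    return out
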