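import numpy as np
import pytest

from esport_erp.profiles import default_profiles
from esport_erp.synthetic import SimulationConfig, generate_epochs


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_st_epochs(profiles):
    """Scaled-down ST block: 10 subjects/group, 8 target + 6 non-target."""
    cfg = SimulationConfig(seed=11)
    return generate_epochs(cfg, "ST", profiles, n_targets=8, n_nontargets=6)


@pytest.fixture(scope="session")
def noiseless_separated_epochs(profiles):
    """Noise-free epochs with widely separated components for exact recovery."""
    from dataclasses import replace

    from esport_erp.profiles import ComponentStats

    erp_map = {
        ("MT", "P200"): ComponentStats(12.0, 0.0, 160, 0.0),
        ("MT", "N200"): ComponentStats(8.0, 0.0, 280, 0.0),
        ("MT", "P300"): ComponentStats(20.0, 0.0, 600, 0.0),
    }
    p = {g: replace(profiles[g], erp=erp_map) for g in profiles}
    cfg = SimulationConfig(seed=3, noise_amplitude_uV=0.0, alpha_amplitude_uV=0.0)
    return generate_epochs(cfg, "MT", p, n_targets=4, n_nontargets=2), erp_map


def brute_force_tfce(m, E, H, dh, diagonal=False):
    """Independent per-point cluster-integral TFCE oracle (BFS clusters)."""
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        m = m[None, :]
        squeeze = True
    else:
        squeeze = False
    out = np.zeros_like(m)
    for sign in (1, -1):
        s = sign * m
        top = s.max(initial=0.0)
        if top <= 0:
            continue
        h = dh
        while h <= top + dh / 2:
            supra = s >= h - 1e-9 * max(1.0, h)
            seen = np.zeros_like(supra)
            for i in range(m.shape[0]):
                for j in range(m.shape[1]):
                    if supra[i, j] and not seen[i, j]:
                        stack = [(i, j)]
                        seen[i, j] = True
                        cluster = []
                        while stack:
                            a, b = stack.pop()
                            cluster.append((a, b))
                            for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                                x, y = a + da, b + db
                                if (0 <= x < m.shape[0] and 0 <= y < m.shape[1]
                                        and supra[x, y] and not seen[x, y]):
                                    seen[x, y] = True
                                    stack.append((x, y))
                        inc = len(cluster) ** E * h ** H * dh
                        for a, b in cluster:
                            out[a, b] += sign * inc
            h += dh
    return out[0] if squeeze else out
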