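"""Independent Metropolis Monte-Carlo sampler of the chain potential.

Used as the equilibrium oracle for the Langevin integrator: it shares the
energy function (which is validated separately against finite differences)
but samples configuration space by pivot + crankshaft moves instead of
dynamics, so agreement of ensemble averages checks the thermostat and
integrator, not the force field.
"""

import numpy as np

from lcrsim._kernels import KB
from lcrsim.forcefield import ForceField


def _rotation_matrix(axis, angle):
    axis = axis / np.linalg.norm(axis)
    a = np.cos(angle / 2.0)
    b, c, d = -axis * np.sin(angle / 2.0)
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
            [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
            [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
        ]
    )


def sample_ree2(system, ff_params, temperature, n_moves, seed,
                burn_in_fraction=0.2, sample_every=50):
    """Mean squared end-to-end distance from pivot/crankshaft Metropolis MC."""
    rng = np.random.default_rng(seed)
    ff = ForceField(system, ff_params)
    kT = KB * temperature
    pos = system.positions.copy()
    n = len(pos)
    energy, _ = ff.energy_forces(pos)
    samples = []
    burn = int(n_moves * burn_in_fraction)
    accepted = 0
    for move in range(n_moves):
        trial = pos.copy()
        u = rng.random()
        if u < 0.4:
            # pivot: rotate the tail beyond a random bead
            k = int(rng.integers(1, n - 1))
            rot = _rotation_matrix(rng.standard_normal(3),
                                   rng.uniform(-np.pi, np.pi))
            trial[k + 1:] = (trial[k + 1:] - trial[k]) @ rot.T + trial[k]
        elif u < 0.7:
            # crankshaft: rotate one interior bead about its neighbor axis
            k = int(rng.integers(1, n - 1))
            axis = trial[k + 1] - trial[k - 1]
            if np.linalg.norm(axis) < 1e-9:
                continue
            rot = _rotation_matrix(axis, rng.uniform(-np.pi, np.pi))
            trial[k] = (trial[k] - trial[k - 1]) @ rot.T + trial[k - 1]
        else:
            # local displacement: samples bond-length fluctuations too
            k = int(rng.integers(0, n))
            trial[k] += 0.03 * rng.standard_normal(3)
        e_new, _ = ff.energy_forces(trial)
        if e_new <= energy or rng.random() < np.exp(-(e_new - energy) / kT):
            pos, energy = trial, e_new
            accepted += 1
        if move >= burn and move % sample_every == 0:
            samples.append(np.sum((pos[-1] - pos[0]) ** 2))
    samples = np.array(samples)
    return {
        "ree2_mean": float(samples.mean()),
        "ree2_se": float(samples.std(ddof=1) / np.sqrt(max(len(samples) // 20, 1))),
        "acceptance": accepted / n_moves,
        "n_samples": len(samples),
    }
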