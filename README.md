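# swarmdmd

Equation-free analysis of collective motion in Python: simulate zonal
(repulsion / orientation / attraction) schooling, decompose multi-agent
observables with dynamic mode decomposition (plain and with reproducing
kernels), compare labelled motion segments with Koopman spectral kernels,
and probe the wave physics of swarms with dynamic structure factors.

The package is aimed at researchers in collective behaviour, active matter
and sports analytics who want to characterise and classify group dynamics
directly from trajectory data, without fitting an explicit interaction
model.

## What it computes

**Zonal schooling model.** N agents move at constant individual speed
|v_i| in 2-D; each step the heading d_i turns (by at most β) towards a
zonal steering direction: away from neighbours closer than r_r
(repulsion, absolute priority), and otherwise towards the average of an
alignment term (mean neighbour heading within r_o) and an attraction term
(towards neighbours within r_a).  Varying r_o alone yields the swarm,
torus (mill) and parallel regimes, quantified by the order parameters

    polarization      P = || Σ d_i || / N
    angular momentum  M = || Σ u_ic × d_i || / N

**Dynamic mode decomposition.** For a snapshot matrix Y = [y_1 … y_{τ−1}],
Y′ = [y_2 … y_τ], the reduced SVD Y = U Σ V* projects the least-squares
propagator to F̂ = U\*Y′VΣ⁻¹; its eigenpairs (λ_j, w_j) give modes
φ_j = Y′VΣ⁻¹w_j λ_j⁻¹ and the expansion

    y_t ≈ Σ_j φ_j exp(ω_j t) ψ_j,   ω_j = ln(λ_j)/Δt,

so each mode oscillates at f_j = Im ln λ_j / (2πΔt) and grows or decays at
Re ln λ_j / Δt.  The kernel variant performs the same projection in the
RKHS of a Gaussian, linear or polynomial kernel via centred Gram matrices
(kernel PCA), capturing nonlinear (Koopman) spectral components from
low-dimensional data.

**Koopman spectral kernels.** Two fitted segments are compared through the
principal angles between their Koopman-mode subspaces in the shared RKHS,
obtained from a generalized eigenproblem over the mode Gram blocks; the
kernel k(i,j) (product of the cosines) induces the squared distance
d(i,j) = k(i,i) + k(j,j) − 2k(i,j) used for classical MDS embedding and
Gaussian naive-Bayes outcome prediction (median error over stratified
5-fold cross-validation).

**Dynamic structure factors.**  S_L and S_T(q, ω) are the temporal power
spectra of the longitudinal and transverse particle currents
j(q, t) = Σ_i (v_i·q̂) e^{iq·r_i}, averaged over propagation directions; a
linear Brillouin-style peak ridge ω_shift = c|q| identifies sound-like
density waves at speed c.

## Worked example

`examples/schooling_regimes.py` simulates the three regimes (64 agents,
4 m/s, 40 s, 25 m circular arena) and prints their order parameters:

```
swarm     (r_o =  2.0 m): polarization = 0.08, angular momentum = 0.15
torus     (r_o = 10.0 m): polarization = 0.08, angular momentum = 0.82
parallel  (r_o = 13.0 m): polarization = 0.60, angular momentum = 0.06
```

High angular momentum singles out the rotating torus, high polarization
the aligned parallel group; the swarm is low in both.

`examples/game_classification.py` generates 40 synthetic 5-on-5 attack
segments whose score / no-score label is carried by the dynamics of four
critical attacker–defender distances, and classifies them via spectral
kernels:

```
4 critical distances  : median CV error = 0.125 (TP 17, TN 18, FP 2, FN 3)
20 Cartesian coords   : median CV error = 0.625 (TP 4, TN 15, FP 5, FN 16)
```

The distance-dynamics features clearly beat raw coordinates — the point of
feeding the decomposition semantically relevant observables.  The other
examples demonstrate the DMD linear-system oracle, the Koopman spectrum of
a nonlinear oscillator under a quadratic kernel, and the ballistic
dispersion oracle (`fitted c = 4.04 m/s` for agents moving at 4 m/s).

A thin CLI mirrors the pipelines, e.g.

```
swarmdmd simulate --ro 10 --seed 1 --out traj.csv
swarmdmd features --input traj.csv --mode sorted_distance --out seq.csv
swarmdmd dmd --input seq.csv --rank 50 --band 0.5,1.5 --out dmd.json
```

## Layout

- `src/swarmdmd/schooling.py` — zonal simulator, order parameters
- `src/swarmdmd/features.py` — sorted-distance and game-distance observables
- `src/swarmdmd/dmd.py`, `kdmd.py` — plain and kernel decompositions
- `src/swarmdmd/spectral_kernels.py` — principal-angle kernels and distances
- `src/swarmdmd/dsf.py` — dynamic structure factors and dispersion fits
- `src/swarmdmd/embed_classify.py` — classical MDS, naive-Bayes CV
- `src/swarmdmd/synthetic.py` — seed-deterministic fixtures with ground truth
- `src/swarmdmd/io.py`, `cli.py` — CSV/JSON artifacts and the `swarmdmd` CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
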