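# Reference configuration of the brainstem-thalamus-cortex neural mass model.
#
# Units: gains in mV, time constants in seconds, potentials in mV,
# rates in spikes/s, noise variances in (spikes/s)^2.  Connectivity weights
# are dimensionless synaptic coupling constants.
#
# Provenance: kernel and sigmoid constants are the standard neural-mass
# values (Jansen-Rit excitatory kinetics and sigmoid; Wendling-style
# slow/fast cortical GABAergic kinetics).  Thalamic GABAergic and
# cholinergic kernels are slower, reflecting GABA_B-like and muscarinic
# receptor dynamics.  Connectivity weights are calibrated (see
# docs/methods.md): the cholinergic weight PNN->TRC anchors the scale at
# 100, retinal input is a minority share of relay drive but the major
# drive of thalamic interneurons, and corticothalamic feedback dominates
# TRN input.  The four weights C_tde, C_idi, C_ndi, C_dpe are the
# experiment parameters.

populations:
  # brainstem
  s: {gain: 3.25, tau: 0.010}   # SC, glutamatergic
  d: {gain: 8.0, tau: 0.0295}   # PNN, cholinergic source (slow muscarinic kernel)
  # thalamus
  i: {gain: 22.0, tau: 0.0395}   # IN, GABAergic (slow)
  t: {gain: 3.25, tau: 0.010}   # TRC, glutamatergic relay
  n: {gain: 22.0, tau: 0.0298}   # TRN, GABAergic (slow)
  # cortex
  h: {gain: 3.25, tau: 0.010}   # eIN, excitatory interneurons
  p: {gain: 3.25, tau: 0.010}   # PY, pyramidal
  f: {gain: 2.5, tau: 0.008}   # fIN, fast somatic GABAergic (resolvable at the 1/256 s step)
  l: {gain: 22.0, tau: 0.020}   # sIN, slow dendritic GABAergic
  # extrinsic noise channels
  r: {gain: 3.25, tau: 0.010}   # Ret, retinal drive
  c: {gain: 3.25, tau: 0.010}   # Cor, adjacent-cortex drive

sigmoid:
  e0: 2.5      # half-maximum firing rate (spikes/s)
  v0: 6.0      # firing threshold (mV)
  sigma: 0.56  # steepness (1/mV)

noise:
  mu1: 11.07    # retinal mean rate
  eps1: 5.0    # retinal rate variance
  mu2: 220.0    # adjacent-cortex mean rate
  eps2: 484.0    # adjacent-cortex rate variance

connectivity:
  # brainstem afferents
  C_sde: 5.0    # PNN -> SC (excitatory)
  C_spe: 30.12    # PY -> SC (descending)
  C_sre: 3.0    # Ret -> SC
  C_dpe: 78.0    # PY -> PNN (descending glutamatergic; experiment parameter)
  # TRC afferents
  C_tde: 100.0   # PNN -> TRC (M1/M3 cholinergic; experiment parameter)
  C_tse: 5.0    # SC -> TRC
  C_tii: 40.53    # IN -| TRC
  C_tni: 4.03    # TRN -| TRC
  C_tpe: 24.99    # PY -> TRC (corticothalamic)
  C_tre: 27.09    # Ret -> TRC
  # IN afferents
  C_idi: 18.0    # PNN -| IN (M2 cholinergic; experiment parameter)
  C_ise: 5.0    # SC -> IN
  C_iii: 5.04    # IN -| IN
  C_ipe: 60.52    # PY -> IN
  C_ire: 10.77    # Ret -> IN
  # TRN afferents
  C_ndi: 10.0    # PNN -| TRN (M2 cholinergic; experiment parameter)
  C_nte: 180.42    # TRC -> TRN
  C_nni: 1.0    # TRN -| TRN
  C_npe: 10.21    # PY -> TRN (corticothalamic)
  # cortical afferents
  C_pte: 12.19    # TRC -> PY (thalamocortical)
  C_phe: 40.0    # eIN -> PY
  C_pfi: 40.0    # fIN -| PY
  C_pli: 30.0    # sIN -| PY
  C_pce: 1.02    # Cor -> PY (noise)
  C_hpe: 40.0    # PY -> eIN
  C_hte: 10.0    # TRC -> eIN
  C_fpe: 40.0    # PY -> fIN
  C_fte: 10.0    # TRC -> fIN
  C_fli: 10.0    # sIN -| fIN
  C_lpe: 30.0    # PY -> sIN
  C_lte: 10.0    # TRC -> sIN
  C_lfi: 10.0    # fIN -| sIN

simulation:
  dt: 0.00390625        # 1/256 s
  duration: 120.0       # s
  transient: 20.0       # s discarded before analysis
  seed: 42
  n_realizations: 500   # batch size for amplitude distributions
  blowup_bound: 1000000.0   # |state| (mV) beyond this aborts with diagnostics

experiments:
  # canonical cholinergic-deficiency sweeps: parameter, descending grid, exemplars
  C_tde: {start: 100.0, stop: 60.0, step: 1.0, exemplars: [100.0, 82.0, 70.0, 60.0]}
  C_idi: {start: 18.0, stop: 1.0, step: 0.5, exemplars: [10.0, 6.0, 3.0, 1.0]}
  C_ndi: {start: 10.0, stop: 0.5, step: 0.25, exemplars: [7.0, 3.0, 1.5, 0.5]}
  C_dpe: {start: 78.0, stop: 38.0, step: 1.0, exemplars: [65.0, 48.0, 41.0, 38.0]}
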