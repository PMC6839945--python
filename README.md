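# coopnet

A spiking-network model of cooperative NMDAR recruitment at feedback
synapses onto a PV+ interneuron, together with the dendritic-integration
nonlinearity statistic and a simplified multicompartmental PV+ cell model
used to study stratum-dependent supralinear summation.

The package has three layers:

1. **Network model** — 250 Izhikevich pyramidal cells reciprocally coupled
   to a fast-spiking interneuron through bi-exponential AMPA/NMDA/GABA
   conductances. Co-active feedback synapses interact through a Gaussian
   Toeplitz distance matrix over afferent index space: each afferent owns a
   local membrane-patch voltage that gates its NMDA conductance, so spikes
   clustered in input space cooperatively relieve the Mg block. External
   drive is an OU-modulated inhomogeneous Poisson process shaped by a
   clustered or dispersed receptive-field profile, optionally
   theta-modulated. One subnetwork (gamma/charge experiments) or two
   mutually inhibiting subnetworks (competition and flip experiments) can
   be simulated (`coopnet.network_sim`).
2. **Analysis** — NMDA/AMPA charge per principal spike, winner spike
   ratios, windowed dominance and flip rates, gamma metrics, per-cycle
   assembly width (`coopnet.assembly_analysis`); the percent-nonlinearity
   statistic with arithmetic-sum construction, Savitzky-Golay smoothing,
   peak and time-integral measures (`coopnet.nonlinearity_metrics`).
3. **Compartmental model** — a synthetic branching PV+ morphology
   (thin/short oriens-like vs thick/long radiatum-like trees, SWC
   round-trip), d-lambda discretization, Crank-Nicolson integration on the
   tree with Wang-Buzsaki Na/K channels, membrane-resistance calibration to
   a 78 MOhm input resistance, and an in-silico glutamate-uncaging protocol
   with condition toggles (NMDA block, Na block, regional NMDA/AMPA ratio
   manipulation, within- vs across-dendrite placement)
   (`coopnet.compartmental`).

Ground-truth-known fixtures for every analysis stage live in
`coopnet.synthetic_data`.

## CLI

```bash
coopnet simulate config.yaml -o record.h5 --spikes-csv spikes.csv
coopnet calibrate config.yaml            # drive multiplier for the gamma regime
coopnet analyze record.h5 -o metrics.csv
coopnet sweep config.yaml --nmdar-scales 0.25,1.0 -o fliprates.csv
coopnet nonlin traces.csv -o nonlinearity.csv
coopnet fixtures --kind uepsp -o fixture.csv
```

Config files are plain YAML mirroring `coopnet.network_sim.NetworkConfig`;
omitted keys take the published parameter-table defaults. An empty file is
a valid config (all defaults).

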