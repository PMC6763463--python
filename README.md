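# endorecycle

Quantification pipelines for photoactivation pulse-chase microscopy of
receptor trafficking: sorting of endocytosed cargo into Rab-labelled
endosomes, recycling back to the plasma membrane, vesicle–plasma-membrane
fusion in TIRF movies, and endosome spatial organisation — together with a
seeded synthetic time-lapse simulator that provides ground truth for every
stage.

## Who this is for

Cell biologists and image analysts working with photoactivatable or
photoswitchable fluorescent proteins (PA-mCherry, PS-CFP2) who need
reproducible, scriptable versions of the common pulse-chase readouts:

- **Endosomal incorporation** — after photoactivating cargo in a region of
  interest, what fraction of the labelled pool sits inside a marker-defined
  compartment (e.g. Rab4/Rab5/Rab11a endosomes) at each timepoint?
- **Plasma-membrane recycling** — after photoactivating cargo inside an
  intracellular compartment, how fast does signal accumulate at the plasma
  membrane?
- **Fusion and co-fusion** — how many vesicle fusion events occur per
  minute in TIRF movies, and what fraction carry a second marker?
- **Spatial organisation** — intensity-weighted dispersion of a marker
  around the cell centre of mass, and particle circularity.
- **Time of divergence** — at which timepoint do two experimental
  conditions' per-cell traces begin to differ and stay different?

## Core quantities

For a photoactivated-cargo channel $I_{PA}$ with thresholded mask $M_{PA}$
and a compartment-marker mask $M_{R}$, the incorporation readout per frame is

$$\%\,\text{incorporated}(t) = 100 \cdot
  \frac{\sum_{p \in M_{PA} \cap M_R} I_{PA}(p, t)}
       {\sum_{p \in M_{PA}} I_{PA}(p, t)}$$

Dispersion of an intensity image $I$ about its weighted centroid $c$ is

$$D = \frac{\sum_i I_i\, \lVert p_i - c \rVert}{\sum_i I_i}
  \quad [\mu m],$$

circularity of a segmented particle is $4\pi A / P^2$ (Crofton perimeter
estimate, capped at 1), and a fusion event "contains" a partner protein when
the mean of the last three frames' maximum partner intensity falls more than
15 % below the initial frame's maximum. The time of divergence of two groups
of traces is the first timepoint after which the two-sided Wilcoxon rank-sum
p-value stays at or below the significance level for every later timepoint.

The nearest-neighbour colocalization readout reports the percentage of
channel-A vesicles whose nearest channel-B vesicle lies within 320 nm, with
a randomized control that repositions the A vesicles uniformly over the cell
mask.

## Worked example

The two half-maximal times measured by the sorting and recycling assays
combine into the total time cargo needs to return to the cell surface. With
the half-maximal sorting time into the recycling compartment of 186.6 s and
the compartment-to-membrane half-time of 375 s:

```python
>>> from endorecycle import total_recycling_halftime
>>> from endorecycle.sortquant import format_minutes_seconds
>>> total = total_recycling_halftime(186.6, 375.0)
>>> total
561.6
>>> format_minutes_seconds(total)
'9 min 21.6 s'
```

i.e. half of the endocytosed receptor pool is back at the plasma membrane
after roughly nine and a half minutes.

A full simulated sorting round:

```python
>>> import numpy as np
>>> from endorecycle import (SortingSimParams, simulate_sorting_assay,
...                          endosomal_incorporation_trace)
>>> params = SortingSimParams()        # 200 vesicles, k_in=0.02/s, k_out=0.005/s, SNR 5
>>> movie, truth = simulate_sorting_assay(params, seed=1)
>>> trace = endosomal_incorporation_trace(movie, "pa_cargo", "marker")
>>> float(np.nanmax(np.abs(trace.values - 100 * truth.occupancy_fraction)))
6.832809601888741
```

The measured incorporation percentage stays within ~7 percentage points of
the true compartment occupancy at every one of the 150 frames.

Pipelines can also be run end to end from the shell:

```bash
endorecycle run sorting --seed 1 --out out/
endorecycle run divergence --seed 1 --out out/
```

Each run writes a traces CSV and a `summary.json` with a provenance block
(seed, config hash, package version); outputs are fully determined by
(config, seed).

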