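# Published reference configuration for the three-class EEG system:
# one-against-one Gaussian SELM on max/std subband features.
strategy: OAO
kernel:
  family: gaussian
  two_sigma_sq: 500.0
C: 5.0
epsilon: 0.001
folds: 4
window: 512
hop: 256
fs: 173.61
bandpass_order: 4
class_list: [A, D, E]
# Alternative kernels/strategies used in the comparison experiments:
alternatives:
  polynomial:
    C: 10.0
    degree: 4          # OAO / DAG / BT
    degree_oaa_ecoc: 3 # OAA / ECOC (with C = 10)
  gaussian_oaa_ecoc:
    C: 5.0
    two_sigma_sq: 600.0
grids:
  C: [0.1, 0.5, 1, 2, 5, 10, 20, 30]
  two_sigma_sq: [1, 5, 10, 60, 100, 200, 300, 400, 500, 600, 700, 800]
  m: [1, 2, 3, 4, 5, 10, 20]
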