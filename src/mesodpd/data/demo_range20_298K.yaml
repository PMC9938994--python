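comment: synthetic demo set, range 20, 298.0 K
reference_temperature: 298.0
rho: 3.0
types:
- name: Me
  volume_A3: 38.0
  molar_mass: 16.04
- name: Et
  volume_A3: 55.5902012706139
  molar_mass: 30.07
- name: Me2O
  volume_A3: 55.059350242698684
  molar_mass: 46.07
- name: MeOH
  volume_A3: 45.0
  molar_mass: 32.04
- name: H2O
  volume_A3: 30.0
  molar_mass: 18.02
repulsion:
- - 24.833333333333332
  - 25.633333333333333
  - 29.633333333333333
  - 32.83333333333333
  - 40.83333333333333
- - 25.633333333333333
  - 24.833333333333332
  - 30.43333333333333
  - 33.63333333333333
  - 42.43333333333333
- - 29.633333333333333
  - 30.43333333333333
  - 24.833333333333332
  - 23.23333333333333
  - 15.233333333333334
- - 32.83333333333333
  - 33.63333333333333
  - 23.23333333333333
  - 24.833333333333332
  - 4.833333333333336
- - 40.83333333333333
  - 42.43333333333333
  - 15.233333333333334
  - 4.833333333333336
  - 24.833333333333332
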