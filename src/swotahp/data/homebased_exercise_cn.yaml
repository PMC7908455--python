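# Bundled case study: development strategy of home-based exercise in China.
# Thirteen SWOT factors identified by a ten-member expert panel, with one
# pairwise comparison matrix per group on the Saaty 1-9 scale and estimated
# strengths on the 0-5 scale.
title: Development strategy of home-based exercise in China (SWOT-AHP)
analyst: expert panel (n = 10)
date: "2021-01"
options:
  reciprocity_tol: 1.0e-6
  strict_saaty: false
  cr_gate: error
  rounding: 4
  theta_rounding: 2
groups:
  S:
    factors:
      - id: S1
        label: Construction of a leading sports nation
        description: >-
          National policy drive that promotes the sports industry and
          popular participation.
        strength: 5
      - id: S2
        label: Increased awareness of exercise
        description: People increasingly recognize the importance of physical health.
        strength: 4
      - id: S3
        label: Time freedom
        description: Exercising at home fits office workers' schedules.
        strength: 3
      - id: S4
        label: Low cost and convenient
        description: >-
          Light or no equipment, independent of weather and travel.
        strength: 2
    matrix:
      - [1, 2, 4, 5]
      - ["1/2", 1, 3, 4]
      - ["1/4", "1/3", 1, 2]
      - ["1/5", "1/4", "1/2", 1]
  W:
    factors:
      - id: W1
        label: Limited space leads to fewer sports methods
        description: Simple lightweight equipment restricts the exercise repertoire.
        strength: 3
      - id: W2
        label: Monotonous and boring form of exercise
        description: Home routines are less engaging and boredom sets in easily.
        strength: 2
      - id: W3
        label: Less theoretical research and insufficient professional talents
        description: >-
          Few targeted studies and a shortage of cross-disciplinary
          professionals.
        strength: 4
    matrix:
      - [1, 2, "1/4"]
      - ["1/2", 1, "1/3"]
      - [4, 3, 1]
  O:
    factors:
      - id: O1
        label: Support provided by the government
        description: Official guidance promoting scientific home-based exercise.
        strength: 3
      - id: O2
        label: The stable development of sports industry
        description: >-
          Steady growth of the sports industry and the online sports market.
        strength: 2
      - id: O3
        label: The rapid development of intelligent sports
        description: >-
          Wearables, smart equipment, VR, and AI motion technology expanding
          into home settings.
        strength: 5
    matrix:
      - [1, 3, "1/4"]
      - ["1/3", 1, "1/6"]
      - [4, 6, 1]
  T:
    factors:
      - id: T1
        label: Noise
        description: Exercise at home can disturb neighbors.
        strength: 1
      - id: T2
        label: Easy to be slack at home
        description: The home environment invites slacking off.
        strength: 3
      - id: T3
        label: Fading enthusiasm for home-based exercise
        description: Enthusiasm fades as outdoor venues reopen.
        strength: 4
    matrix:
      - [1, "1/3", "1/4"]
      - [3, 1, "1/2"]
      - [4, 2, 1]
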