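C: 12.0
g_leak: 0.105
E_leak: -60.59446748105934
E_Ca: 60.0
calcium:
  F: 0.515
  tau_Ca: 300.0
  C0: 0.5
channels:
  h:
    gbar: 0.219
    reversal: -20.0
    activation_exponent: 1
    activation:
      half: -70.0
      slope: 6.0
      tau_base: 50.0
      tau_amplitude: 200.0
      tau_half: -42.2
      tau_slope: -8.73
  CaT:
    gbar: 2.25
    reversal: E_Ca
    activation_exponent: 3
    activation:
      half: -25.0
      slope: -7.2
      tau_base: 1.0
      tau_amplitude: 9.0
      tau_half: -58.0
      tau_slope: 17.0
    inactivation:
      half: -36.0
      slope: 7.0
      tau_base: 80.0
      tau_amplitude: 10.0
      tau_half: -50.0
      tau_slope: 17.0
  CaS:
    gbar: 5.4
    reversal: E_Ca
    activation_exponent: 3
    activation:
      half: -22.0
      slope: -8.5
      tau_base: 16.0
      tau_amplitude: -13.1
      tau_half: -25.1
      tau_slope: -16.4
  KCa:
    gbar: 150.0
    reversal: -80.0
    activation_exponent: 4
    activation:
      half: -51.0
      slope: -8.0
      tau_base: 90.3
      tau_amplitude: -75.1
      tau_half: -46.0
      tau_slope: -22.7
    calcium_coupled: true
    ca_half: 30.0
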