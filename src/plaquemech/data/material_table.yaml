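# Ground-truth material parameters and search bounds per tissue class.
# Moduli in kPa. "assigned" is the value used to generate verification
# targets; "range" is the optimizer search interval (absent for parameters
# that are held fixed in every recovery mode). The calcium C10 range applies
# only when calcium is included in the recovery (volume fraction > 1%).
artery:
  volume_pct: 64.6
  E:   {assigned: 300.0,  range: [100.0, 3000.0]}
  C10: {assigned: 5.64,   range: [1.0, 10.0]}
  C20: {assigned: 1812.0, range: [1000.0, 10000.0]}
  C30: {assigned: 162.0}
mixed:
  volume_pct: 2.9
  E:   {assigned: 500.0,  range: [100.0, 3000.0]}
  C10: {assigned: 25.0,   range: [10.0, 100.0]}
  C20: {assigned: 850.0,  range: [100.0, 1000.0]}
  C30: {assigned: 300.0}
fibrous:
  volume_pct: 19.3
  E:   {assigned: 1200.0, range: [100.0, 3000.0]}
  C10: {assigned: 54.0,   range: [10.0, 100.0]}
  C20: {assigned: 2200.0, range: [1000.0, 10000.0]}
  C30: {assigned: 42.5}
lipid:
  volume_pct: 13.0
  E:   {assigned: 15.0,   range: [5.0, 200.0]}
  C10: {assigned: 18.0,   range: [10.0, 100.0]}
  C20: {assigned: 207.0,  range: [100.0, 1000.0]}
  C30: {assigned: 422.0}
calcium:
  volume_pct: 0.3
  E:   {assigned: 5000.0}
  C10: {assigned: 1270.0, range: [127.0, 12700.0]}
  C20: {assigned: 0.0}
  C30: {assigned: 0.0}
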