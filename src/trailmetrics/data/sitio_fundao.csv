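route,altitude_end_m,distance_km,speed_kmh,direction
start,462,0,,
Route 1,462.3,0.1,2,uphill
Route 2,468,0.1,2,uphill
Route 3,450,0.2,2,downhill
Route 4,455,0.1,2,uphill
Route 5,468,0.1,2,uphill
Route 6,471,0.1,2,uphill
Route 7,451,0.3,2,downhill
Route 8,464,0.4,2,uphill
Route 9,469,0.2,2,uphill
Route 10,476,0.1,2,uphill
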