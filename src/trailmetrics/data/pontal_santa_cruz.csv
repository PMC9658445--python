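route,altitude_end_m,distance_km,speed_kmh,direction
start,662,0,,
Route 1,672,0.05,2,uphill
Route 2,683,0.05,2,uphill
Route 3,690,0.04,2,uphill
Route 4,700,0.04,2,uphill
Route 5,710,0.04,2,uphill
Route 6,723,0.04,2,uphill
Route 7,731,0.04,2,uphill
Route 8,723,0.04,2,downhill
Route 9,710,0.04,2,downhill
Route 10,700,0.04,2,downhill
Route 11,690,0.04,2,downhill
Route 12,683,0.04,2,downhill
Route 13,672,0.05,2,downhill
Route 14,662,0.05,2,downhill
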