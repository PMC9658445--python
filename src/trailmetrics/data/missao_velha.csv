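route,altitude_end_m,distance_km,speed_kmh,direction
start,333,0,,
Route 1,341,0.1,3,uphill
Route 2,337,0.05,3,downhill
Route 3,341,0.05,3,uphill
Route 4,336,0.3,3,downhill
Route 5,346,0.2,3,uphill
Route 6,325,0.4,3,downhill
Route 7,333,0.6,3,uphill
Route 8,324,0.1,3,downhill
Route 9,337,0.3,3,uphill
Route 10,319,0.3,3,downhill
Route 11,326,0.2,3,uphill
Route 12,320,0.1,3,downhill
Route 13,332,0.5,3,uphill
Route 14,344,0.1,3,uphill
Route 15,347,0.2,3,uphill
Route 16,333,0.5,3,downhill
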