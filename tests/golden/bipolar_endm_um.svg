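<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="34.1818" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="382.9091" cy="370.3977" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="382.9091" y1="370.3977" x2="340.1818" y2="296.3919" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="417.0909" cy="429.6023" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="417.0909" y1="429.6023" x2="459.8182" y2="503.6081" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 340.1818 503.6081 A 119.6364 119.6364 0 0 0 503.6081 340.1818" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="340.1818" y1="503.6081" x2="297.4545" y2="577.6139" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 222.3861 502.5455 A 205.0909 205.0909 0 0 0 502.5455 577.6139" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="222.3861" y1="502.5455" x2="148.3803" y2="545.2727" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 109.4545 400.0000 A 290.5455 290.5455 0 0 0 254.7273 651.6197" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="109.4545" y1="400.0000" x2="24.0000" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="254.7273" y1="651.6197" x2="212.0000" y2="725.6256" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="502.5455" y1="577.6139" x2="545.2727" y2="651.6197" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="503.6081" y1="340.1818" x2="577.6139" y2="297.4545" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 605.0909 400.0000 A 205.0909 205.0909 0 0 0 502.5455 222.3861" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="605.0909" y1="400.0000" x2="690.5455" y2="400.0000" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="502.5455" y1="222.3861" x2="545.2727" y2="148.3803" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
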