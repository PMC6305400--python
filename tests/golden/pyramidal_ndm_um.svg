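<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.0000" height="800.0000" viewBox="0 0 800.0000 800.0000">
<circle cx="400.0000" cy="400.0000" r="34.1818" fill="none" stroke="#000000" stroke-width="1.0000"/>
<circle cx="375.8298" cy="375.8298" r="8.5455" fill="#0000ff" stroke="none"/>
<line x1="375.8298" y1="375.8298" x2="315.4043" y2="315.4043" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 363.0303 286.2191 A 119.6364 119.6364 0 0 0 293.4032 345.6862" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="363.0303" y1="286.2191" x2="336.6234" y2="204.9470" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 367.9167 197.4341 A 205.0909 205.0909 0 0 0 306.8907 217.2627" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="367.9167" y1="197.4341" x2="354.5487" y2="113.0316" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="306.8907" y1="217.2627" x2="268.0951" y2="141.1221" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="293.4032" y1="345.6862" x2="217.2627" y2="306.8907" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 234.0780 279.4506 A 205.0909 205.0909 0 0 0 197.4341 367.9167" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="234.0780" y1="279.4506" x2="164.9438" y2="229.2217" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 194.5533 194.5533 A 290.5455 290.5455 0 0 0 141.1221 268.0951" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="194.5533" y1="194.5533" x2="134.1279" y2="134.1279" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="141.1221" y1="268.0951" x2="64.9815" y2="229.2996" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="197.4341" y1="367.9167" x2="113.0316" y2="354.5487" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="375.8298" cy="424.1702" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="375.8298" y1="424.1702" x2="315.4043" y2="484.5957" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 284.4401 430.9642 A 119.6364 119.6364 0 0 0 340.1818 503.6081" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="284.4401" y1="430.9642" x2="201.8974" y2="453.0814" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="340.1818" y1="503.6081" x2="297.4545" y2="577.6139" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 254.9788 545.0212 A 205.0909 205.0909 0 0 0 346.9186 598.1026" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="254.9788" y1="545.0212" x2="194.5533" y2="605.4467" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="346.9186" y1="598.1026" x2="324.8013" y2="680.6454" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="424.1702" cy="424.1702" r="8.5455" fill="#00ffff" stroke="none"/>
<line x1="424.1702" y1="424.1702" x2="484.5957" y2="484.5957" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 445.7829 510.5296 A 119.6364 119.6364 0 0 0 510.5296 445.7829" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="445.7829" y1="510.5296" x2="478.4849" y2="589.4793" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="510.5296" y1="445.7829" x2="589.4793" y2="478.4849" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<circle cx="424.1702" cy="375.8298" r="8.5455" fill="#ff0000" stroke="none"/>
<line x1="424.1702" y1="375.8298" x2="484.5957" y2="315.4043" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 510.5296 354.2171 A 119.6364 119.6364 0 0 0 445.7829 289.4704" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="510.5296" y1="354.2171" x2="589.4793" y2="321.5151" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 601.1501 359.9887 A 205.0909 205.0909 0 0 0 570.5269 286.0576" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="601.1501" y1="359.9887" x2="684.9627" y2="343.3174" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="570.5269" y1="286.0576" x2="641.5797" y2="238.5816" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="445.7829" y1="289.4704" x2="478.4849" y2="210.5207" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<path d="M 513.9424 229.4731 A 205.0909 205.0909 0 0 0 440.0113 198.8499" fill="none" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="513.9424" y1="229.4731" x2="561.4184" y2="158.4203" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
<line x1="440.0113" y1="198.8499" x2="456.6826" y2="115.0373" stroke="#000000" stroke-width="1.2000" stroke-linecap="round"/>
</svg>
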